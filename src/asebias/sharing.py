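"""Cross-sample set logic for ASE results.

Classifies each significant feature (gene or SNV) by how it is shared
across individuals — shared by at least a minimum fraction (two-thirds by
default, i.e. "4 or more of 6"), private to a single individual, or
restricted to one sex — and, across tissues, finds tissue-specific and
pervasive features. Operates purely on per-sample significant sets plus a
sample manifest; absence from a sample's result universe counts as
non-significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_FRACTION_DEFAULT = 2.0 / 3.0

CLASSIFICATIONS = ("shared", "female_only", "male_only", "private", "multi")


@dataclass(frozen=True)
class SampleKey:
    individual_id: str
    sex: str = "unknown"  # F, M, or unknown
    tissue: str = ""


def shared_threshold(n_samples: int, min_fraction: float = MIN_FRACTION_DEFAULT) -> int:
    """Minimum number of significant samples for "shared" (ceiling rule).

    With 6 samples and the 2/3 default this is 4; with 5 available samples
    (e.g. one failed QC) it is still 4 — the rule applies to the samples
    actually present.
    """
    return math.ceil(min_fraction * n_samples)


def shared_features(
    significant: dict[str, set],
    sex_of: dict[str, str] | None = None,
    scores: dict[tuple[str, str], float] | None = None,
    min_fraction: float = MIN_FRACTION_DEFAULT,
) -> pd.DataFrame:
    """Classify features by their sharing pattern across samples.

    ``significant`` maps sample id -> set of significant features; the
    feature universe is the union. Classification per feature (mutually
    exclusive, checked in this order):

    * ``shared`` — significant in >= ceil(min_fraction * n_samples) samples;
    * ``female_only`` / ``male_only`` — significant in every sample of one
      sex and none of the other (requires a ``sex_of`` manifest);
    * ``private`` — significant in exactly one sample;
    * ``multi`` — any other multi-sample pattern.

    ``scores`` maps (sample, feature) -> effect size; the mean effect is the
    unweighted mean across the samples where the feature is significant.
    """
    if len(significant) < 2:
        raise ValueError("sharing requires at least two samples")
    samples = sorted(significant)
    sex_of = sex_of or {}
    females = {s for s in samples if sex_of.get(s) == "F"}
    males = {s for s in samples if sex_of.get(s) == "M"}
    threshold = shared_threshold(len(samples), min_fraction)
    universe = sorted(set().union(*significant.values()))
    rows = []
    for feature in universe:
        in_samples = {s for s in samples if feature in significant[s]}
        n = len(in_samples)
        if n >= threshold:
            cls = "shared"
        elif females and in_samples == females and not (in_samples & males):
            cls = "female_only"
        elif males and in_samples == males and not (in_samples & females):
            cls = "male_only"
        elif n == 1:
            cls = "private"
        else:
            cls = "multi"
        if scores:
            effs = [scores[(s, feature)] for s in in_samples if (s, feature) in scores]
            mean_eff = float(np.mean(effs)) if effs else np.nan
        else:
            mean_eff = np.nan
        rows.append((feature, cls, n, ",".join(sorted(in_samples)), mean_eff))
    return pd.DataFrame(
        rows, columns=["feature", "classification", "n_significant",
                       "samples", "mean_effect"])


def membership_matrix(significant: dict[str, set]) -> pd.DataFrame:
    """Boolean feature x sample matrix (UpSet-plot compatible)."""
    samples = sorted(significant)
    universe = sorted(set().union(*significant.values()))
    data = {s: [f in significant[s] for f in universe] for s in samples}
    return pd.DataFrame(data, index=universe)


def tissue_specific_sets(
    shared_by_tissue: dict[str, set],
) -> dict[str, set]:
    """Partition shared features into per-tissue-specific / pervasive / multi.

    Input: per-tissue sets of features passing the sharing rule within that
    tissue. A feature shared in exactly one tissue is specific to it; shared
    in every tissue is pervasive; anything in between is multi-tissue.
    Returned dict has one key per tissue plus ``pervasive`` and
    ``multi_tissue``.
    """
    if len(shared_by_tissue) < 2:
        raise ValueError("tissue specificity requires at least two tissues")
    tissues = sorted(shared_by_tissue)
    out: dict[str, set] = {t: set() for t in tissues}
    out["pervasive"] = set()
    out["multi_tissue"] = set()
    for feature in set().union(*shared_by_tissue.values()):
        hits = [t for t in tissues if feature in shared_by_tissue[t]]
        if len(hits) == 1:
            out[hits[0]].add(feature)
        elif len(hits) == len(tissues):
            out["pervasive"].add(feature)
        else:
            out["multi_tissue"].add(feature)
    return out


def sharing_report_tsv(report: pd.DataFrame, path, grouping: str = "individual") -> None:
    """Write the long-format sharing report with a grouping label column."""
    out = report.copy()
    out.insert(1, "grouping", grouping)
    out.to_csv(path, sep="\t", index=False)
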