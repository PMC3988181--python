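"""Probe-set to gene mapping and outlier-array screening.

These are the bookkeeping steps that precede network construction when the
input is a probe-level microarray compendium: collapse probe sets onto gene
models using perfect-match probe counts, drop platform control probe sets,
and flag whole arrays whose intensity distribution is an outlier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProbeGeneMap",
    "map_probe_sets",
    "drop_control_probe_sets",
    "flag_outlier_arrays",
]


@dataclass
class ProbeGeneMap:
    """Outcome of probe-set -> gene assignment.

    ``assignments`` holds the surviving one-to-one map; ``removed_multi``
    lists probe sets discarded for mapping equally well to several genes;
    ``unmapped`` lists probe sets with no gene reaching the perfect-match
    threshold; ``duplicate_resolutions`` records, per gene hit by several
    assigned probe sets, which set was kept and which were discarded.
    """

    assignments: dict[str, str]
    removed_multi: list[str]
    unmapped: list[str]
    duplicate_resolutions: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [(ps, g, "assigned") for ps, g in self.assignments.items()]
        rows += [(ps, "", "removed_multi") for ps in self.removed_multi]
        rows += [(ps, "", "unmapped") for ps in self.unmapped]
        for gene, (_kept, discarded) in self.duplicate_resolutions.items():
            rows += [(ps, gene, "duplicate_discarded") for ps in discarded]
        return pd.DataFrame(rows, columns=["probe_set_id", "gene_id", "status"]).sort_values(
            ["status", "probe_set_id"], ignore_index=True
        )


def map_probe_sets(hits: pd.DataFrame, seed: int = 0, min_perfect: int = 4,
                   perfect_only: bool = True) -> ProbeGeneMap:
    """Assign each probe set to at most one gene by perfect-probe counts.

    A gene is a candidate for a probe set when at least ``min_perfect``
    distinct probes of the set align to it perfectly ("more than three" with
    the default of 4).  A probe set with a unique best candidate is assigned
    to it; a tie at the maximum count removes the set; no candidate leaves it
    unmapped.  When several assigned probe sets land on the same gene, one is
    kept uniformly at random (seeded) and the rest are discarded.

    ``perfect_only`` restricts the best-hit comparison to perfect matches
    (the default convention; set False to count all listed probes).
    """
    if hits.empty:
        raise ValueError("hit table is empty")
    use = hits if not perfect_only else hits[hits["perfect"] == 1]
    counts = (
        use.drop_duplicates(["probe_set_id", "probe_id", "gene_id"])
        .groupby(["probe_set_id", "gene_id"], sort=True)["probe_id"]
        .nunique()
    )

    assignments: dict[str, str] = {}
    removed_multi: list[str] = []
    unmapped: list[str] = []
    all_sets = sorted(hits["probe_set_id"].unique())
    for probe_set in all_sets:
        try:
            per_gene = counts.loc[probe_set]
        except KeyError:
            unmapped.append(probe_set)
            continue
        per_gene = per_gene[per_gene >= min_perfect]
        if per_gene.empty:
            unmapped.append(probe_set)
            continue
        best = per_gene.max()
        winners = sorted(per_gene.index[per_gene == best])
        if len(winners) > 1:
            removed_multi.append(probe_set)
        else:
            assignments[probe_set] = winners[0]

    # resolve genes claimed by several assigned probe sets
    rng = np.random.default_rng(seed)
    by_gene: dict[str, list[str]] = {}
    for ps, gene in assignments.items():
        by_gene.setdefault(gene, []).append(ps)
    duplicate_resolutions: dict[str, tuple[str, list[str]]] = {}
    for gene in sorted(by_gene):
        sets = sorted(by_gene[gene])
        if len(sets) == 1:
            continue
        kept = sets[int(rng.integers(len(sets)))]
        discarded = [ps for ps in sets if ps != kept]
        for ps in discarded:
            del assignments[ps]
        duplicate_resolutions[gene] = (kept, discarded)

    return ProbeGeneMap(assignments, removed_multi, unmapped, duplicate_resolutions)


def drop_control_probe_sets(ids: pd.Index | list[str], prefix: str = "AFFX") -> list[str]:
    """Probe-set ids with platform control sets (by id prefix) removed."""
    return [i for i in ids if not str(i).startswith(prefix)]


def flag_outlier_arrays(x: pd.DataFrame, k: float = 1.5) -> list[str]:
    """Samples whose intensity distribution is a boxplot-fence outlier.

    Per sample the statistic is the two-sample Kolmogorov-Smirnov distance
    between that sample's intensities and the pooled intensities of all
    samples; samples with a distance above ``Q3 + k * IQR`` of the per-sample
    distances are flagged (order of columns preserved).
    """
    if x.shape[1] < 4:
        raise ValueError("outlier screening needs at least 4 samples")
    pooled = x.to_numpy().ravel()
    d = np.array(
        [stats.ks_2samp(x[c].to_numpy(), pooled, method="asymp").statistic for c in x.columns]
    )
    q1, q3 = np.percentile(d, [25, 75])
    iqr = q3 - q1
    if not np.isfinite(k):
        fence = np.inf
    else:
        fence = q3 + k * iqr
    flagged = [c for c, dist in zip(x.columns, d) if dist > fence]
    if flagged:
        warnings.warn(f"flagged {len(flagged)} outlier array(s): {flagged}", stacklevel=2)
    return flagged
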