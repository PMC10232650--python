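"""Differential circRNA expression and circle-validation assay summaries.

Differential calls follow a fold-change-first design: tumor/normal fold
change on CPM-normalized junction counts (pseudocount 0.5 CPM), with an
inclusive 2.5-fold gate in either direction, plus a paired exact Wilcoxon
signed-rank p-value and a Benjamini-Hochberg q-value reported as evidence.
With n=4 pairs the smallest attainable exact two-sided p is 2/16 = 0.125,
so at this design size the Wilcoxon test cannot clear conventional
significance on its own; the fold-change gate is the primary rule and p/q
annotate it.

The Wilcoxon test is exact by enumeration of all 2^n sign assignments
(implemented as a subset-sum recursion over mid-ranked |differences|, which
enumerates the same distribution without materialising 2^n terms).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix

FC_THRESHOLD = 2.5
PSEUDOCOUNT_CPM = 0.5


def normalize_cpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million junction-library reads: count / library_size * 1e6."""
    lib = pd.Series(matrix.library_sizes, dtype=float)
    missing = [c for c in matrix.counts.columns if c not in lib.index]
    if missing:
        raise ValueError(f"no library size for samples {missing}")
    lib = lib.reindex(matrix.counts.columns)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples {bad}")
    return matrix.counts / lib * 1e6


def wilcoxon_signed_rank_exact(differences) -> float:
    """Exact two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped before ranking; ties among |differences|
    get mid-ranks. The null distribution of W+ is enumerated over all 2^n
    sign assignments; the two-sided p is 2*min(P(W+<=w), P(W+>=w)), capped
    at 1. All differences zero gives p=1 with a warning.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("no paired differences")
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    if n > 25:
        raise ValueError("exact enumeration supported for n <= 25 pairs")
    ranks = rankdata(np.abs(d))  # mid-ranks on ties, possibly half-integral
    r2 = np.rint(2 * ranks).astype(int)  # doubled ranks are exact integers
    w2 = int(np.rint(2 * ranks[d > 0].sum()))
    # subset-sum recursion == enumeration of all 2^n sign assignments
    dist = np.zeros(r2.sum() + 1)
    dist[0] = 1.0
    for r in r2:
        dist[r:] += dist[:-r].copy() if r > 0 else dist.copy()
    total = 2.0**n
    p_le = dist[: w2 + 1].sum() / total
    p_ge = dist[w2:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def differential_circles(
    cpm: pd.DataFrame,
    pairs: list[tuple[str, str]],
    fc_threshold: float = FC_THRESHOLD,
    pseudocount: float = PSEUDOCOUNT_CPM,
) -> pd.DataFrame:
    """Per-circle DE table from CPM values and a (tumor, normal) pairing.

    fold_change = (mean tumor CPM + eps) / (mean normal CPM + eps) with
    eps = ``pseudocount``; direction is 'up' iff fold_change >= threshold
    (inclusive), 'down' iff <= 1/threshold, else 'unchanged'. p-values come
    from the exact paired Wilcoxon test on per-pair CPMs and q-values from
    Benjamini-Hochberg across all tested circles.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    tumor_cols = [t for t, _ in pairs]
    normal_cols = [n for _, n in pairs]
    missing = [c for c in tumor_cols + normal_cols if c not in cpm.columns]
    if missing:
        raise ValueError(f"unpaired/unknown samples in pairing: {missing}")
    mean_t = cpm[tumor_cols].mean(axis=1)
    mean_n = cpm[normal_cols].mean(axis=1)
    fc = (mean_t + pseudocount) / (mean_n + pseudocount)
    direction = pd.Series("unchanged", index=cpm.index)
    direction[fc >= fc_threshold] = "up"
    direction[fc <= 1.0 / fc_threshold] = "down"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero rows legitimately give p=1
        pvals = np.array(
            [
                wilcoxon_signed_rank_exact(
                    cpm.loc[c, tumor_cols].to_numpy()
                    - cpm.loc[c, normal_cols].to_numpy()
                )
                for c in cpm.index
            ]
        )
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "circ_id": cpm.index,
            "mean_tumor_cpm": mean_t.to_numpy(),
            "mean_normal_cpm": mean_n.to_numpy(),
            "fold_change": fc.to_numpy(),
            "direction": direction.to_numpy(),
            "p_value": pvals,
            "q_value": qvals,
        }
    ).set_index("circ_id")


def rnase_r_resistance(
    circ_treated: float,
    circ_untreated: float,
    linear_treated: float,
    linear_untreated: float,
) -> float:
    """RNase R resistance ratio: (circ_t/circ_u) / (lin_t/lin_u).

    A circle surviving digestion better than its cognate linear mRNA gives a
    ratio well above 1 — the hallmark of a covalently closed species.
    """
    if circ_untreated <= 0 or linear_untreated <= 0:
        raise ValueError("untreated counts must be positive")
    if linear_treated == 0:
        warnings.warn("linear species fully depleted; resistance is infinite", stacklevel=2)
        return float("inf")
    return (circ_treated / circ_untreated) / (linear_treated / linear_untreated)


def fraction_localization(nuclear: float, cytoplasmic: float) -> float:
    """Cytoplasmic fraction cyto/(cyto+nuc) from fractionation counts."""
    if nuclear < 0 or cytoplasmic < 0:
        raise ValueError("counts must be non-negative")
    total = nuclear + cytoplasmic
    if total == 0:
        raise ValueError("no molecules observed in either fraction")
    return cytoplasmic / total


# ---------------------------------------------------------------------------
# Sample sheet and output
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str) -> list[tuple[str, str]]:
    """(tumor, normal) pairs from a TSV with columns sample, group, pair_id."""
    sheet = pd.read_csv(path, sep="\t")
    for col in ("sample", "group", "pair_id"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet missing column {col!r}")
    pairs = []
    for pair_id, grp in sheet.groupby("pair_id", sort=True):
        tumors = grp.loc[grp.group == "tumor", "sample"].tolist()
        normals = grp.loc[grp.group == "normal", "sample"].tolist()
        if len(tumors) != 1 or len(normals) != 1:
            raise ValueError(
                f"pair {pair_id!r} must have exactly one tumor and one normal sample"
            )
        pairs.append((tumors[0], normals[0]))
    return pairs


def write_sample_sheet(pairs: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\tpair_id\n")
        for i, (t, n) in enumerate(pairs, 1):
            fh.write(f"{t}\ttumor\t{i}\n{n}\tnormal\t{i}\n")


def write_de_table(de: pd.DataFrame, path: str, header: dict | None = None) -> None:
    """DE table TSV with a reproducibility header of '# key=value' lines."""
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        de.to_csv(fh, sep="\t")
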