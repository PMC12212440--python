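"""Washout-persistence classification of stimulus-induced peaks.

The questions answered here are the chromatin-memory ones: which peaks
(H3K4me1 or ATAC) are induced by each acute stimulus, which of the induced
peaks remain elevated 88 h after cytokine washout under each post-washout
treatment (plain media, anti-IFNγ antibody, ruxolitinib), how the signal
within induced peaks shifts on washout (mean log2 fold change plus a
paired Wilcoxon signed-rank test), and how induced peaks partition into
washout behaviors (augment / persist / decay) by k-means.

Persistence follows the published rule: within the set of peaks induced at
8 h, a peak persists under a treatment iff its washout-vs-unstimulated
contrast keeps a non-negative log2 fold change at FDR < 0.01. The
alternative reading (log2 fold change of washout vs the 8 h peak signal
>= 0) is available via ``persistence_reference="stim_8h"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from . import cluster as _cluster
from .diff import (
    DEFAULT_PRIOR_CPM,
    ContrastResult,
    acute_abundance_filter,
    call_induced,
    condition_mean_cpm,
    log2_fold_change,
    run_contrast,
)
from .matrix import CountMatrix, SampleDesign

__all__ = [
    "classify_persistent",
    "persistence_fraction",
    "washout_shift",
    "paired_wilcoxon",
    "shared_peaks",
    "classify_peaks",
    "PeakMemoryResult",
]

#: washout arm condition label per post-washout treatment (IFNγ pulse)
WASHOUT_ARMS = {
    "media": "ifng_wash_media",
    "anti_ifng_ab": "ifng_wash_ab",
    "ruxolitinib": "ifng_wash_rux",
}


def classify_persistent(
    washout_contrast: ContrastResult,
    induced_ids: set[str],
    fdr_cutoff: float = 0.01,
) -> pd.Series:
    """Persistence calls for induced peaks: l2fc >= 0 and FDR < cutoff.

    The contrast must be post-washout vs the unstimulated baseline.
    Classification is defined only on peaks already called induced at 8 h;
    asking about any other feature raises.
    """
    t = washout_contrast.table.set_index("feature_id")
    missing = induced_ids - set(t.index)
    if missing:
        raise KeyError(
            f"feature {sorted(missing)[0]!r} is not in the washout contrast"
        )
    sub = t.loc[sorted(induced_ids)]
    return (sub["l2fc"] >= 0) & (sub["fdr"] < fdr_cutoff)


def persistence_fraction(calls: pd.DataFrame, treatment: str) -> float:
    """(# induced peaks persistent under ``treatment``) / (# induced peaks)."""
    col = f"persistent_{treatment}"
    if col not in calls.columns:
        raise KeyError(f"no persistence calls for treatment {treatment!r}")
    induced = calls[calls["induced_ifng"]]
    if len(induced) == 0:
        raise ValueError("no induced peaks: persistence fraction undefined")
    return float(induced[col].mean())


def paired_wilcoxon(x, y) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped before ranking; ties are mid-ranked. For
    up to 25 remaining pairs the exact null distribution of the positive
    rank sum is enumerated by convolution; beyond that a normal
    approximation with tie-corrected variance and continuity correction is
    used. All differences zero gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size == 0:
        raise ValueError("need at least one pair")
    d = y - x
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= 25:
        return _exact_signed_rank_p(ranks, w)
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0
    z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def _exact_signed_rank_p(ranks: np.ndarray, w: float) -> float:
    # doubled integer ranks make mid-ranks exact
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = (pmf + shifted) / 2.0
    w2 = int(np.rint(2 * w))
    cdf = float(pmf[: w2 + 1].sum())
    sf = float(pmf[w2:].sum())
    return float(min(1.0, 2.0 * min(cdf, sf)))


def washout_shift(
    cpm_8h,
    cpm_washout,
    prior: float = DEFAULT_PRIOR_CPM,
) -> tuple[np.ndarray, float, float]:
    """Per-peak washout shift: l2fc list, mean l2fc, paired Wilcoxon p.

    Inputs are paired per-peak replicate-mean CPM at 8 h and post-washout
    over the same peak set. The Wilcoxon test is applied to the paired
    log2(CPM + prior) values, i.e. to the signed per-peak shifts.
    """
    a = np.asarray(cpm_8h, dtype=float)
    b = np.asarray(cpm_washout, dtype=float)
    if a.shape != b.shape:
        raise ValueError("cpm_8h and cpm_washout must be paired (same length)")
    l2fc = log2_fold_change(b, a, prior)
    p = paired_wilcoxon(np.log2(a + prior), np.log2(b + prior))
    return l2fc, float(np.mean(l2fc)), p


def shared_peaks(induced_ifng: set[str], induced_lps: set[str]) -> set[str]:
    """Peaks induced by both IFNγ and LPS (set intersection)."""
    return set(induced_ifng) & set(induced_lps)


@dataclass
class PeakMemoryResult:
    """Full peak-memory classification of one count matrix."""

    calls: pd.DataFrame = field(repr=False)
    contrasts: dict[str, ContrastResult] = field(repr=False)
    summary: dict = field(default_factory=dict)
    cluster_table: pd.DataFrame | None = field(default=None, repr=False)
    metadata: dict = field(default_factory=dict)


def classify_peaks(
    matrix: CountMatrix,
    design: SampleDesign,
    l2fc_cutoff: float = 2.0,
    fdr_cutoff: float = 0.01,
    prior: float = DEFAULT_PRIOR_CPM,
    persistence_reference: str = "unstimulated",
    apply_abundance_filter: bool = True,
    cluster_k: int = 3,
    cluster_seed: int = 17,
    cluster_restarts: int = 50,
    cluster_columns: str = "replicates",
) -> PeakMemoryResult:
    """Run the complete peak-memory workflow on one peak count matrix.

    Stages: abundance filter over acute conditions -> induction contrasts
    (IFNγ, LPS, LPS+ruxolitinib at 8 h vs unstimulated) -> induced and
    shared peak sets -> washout contrasts and persistence calls per
    treatment arm -> washout shift statistics -> behavioral k-means of the
    IFNγ-induced peaks.

    ``persistence_reference`` selects the contrast underlying persistence:
    ``"unstimulated"`` (washout vs baseline, significant with l2fc >= 0)
    or ``"stim_8h"`` (washout level at least the 8 h level). The chosen
    mode is recorded in ``metadata``.
    """
    design.validate_against(matrix)
    if persistence_reference not in ("unstimulated", "stim_8h"):
        raise ValueError("persistence_reference must be 'unstimulated' or 'stim_8h'")
    if apply_abundance_filter:
        keep = acute_abundance_filter(matrix, design)
        matrix = matrix.subset_features(keep)

    contrasts: dict[str, ContrastResult] = {}
    for cond in ("ifng_8h", "lps_8h", "lps_rux_8h"):
        contrasts[cond] = run_contrast(matrix, design, cond, "unstim", prior=prior)

    induced: dict[str, np.ndarray] = {}
    for cond, ctr in contrasts.items():
        induced[cond] = call_induced(ctr["l2fc"], ctr["fdr"], l2fc_cutoff, fdr_cutoff)

    fids = np.array(matrix.feature_ids)
    induced_ifng_ids = set(fids[induced["ifng_8h"]])
    induced_lps_ids = set(fids[induced["lps_8h"]])
    shared_ids = shared_peaks(induced_ifng_ids, induced_lps_ids)

    calls = pd.DataFrame(
        {
            "feature_id": fids,
            "induced_ifng": induced["ifng_8h"],
            "induced_lps": induced["lps_8h"],
            "induced_lps_rux": induced["lps_rux_8h"],
            "shared": [f in shared_ids for f in fids],
        }
    )

    arm_conditions = {
        tr: cond for tr, cond in WASHOUT_ARMS.items() if design.samples_in(cond)
    }
    for treatment, cond in arm_conditions.items():
        contrasts[cond] = run_contrast(matrix, design, cond, "unstim", prior=prior)
        if persistence_reference == "unstimulated":
            persistent = classify_persistent(
                contrasts[cond], induced_ifng_ids, fdr_cutoff=fdr_cutoff
            )
            persistent_ids = set(persistent.index[persistent])
        else:
            t8 = contrasts["ifng_8h"].table.set_index("feature_id")
            tw = contrasts[cond].table.set_index("feature_id")
            shift = pd.Series(
                log2_fold_change(tw["mean_cpm_b"], t8["mean_cpm_b"], prior),
                index=t8.index,
            )
            persistent_ids = set(shift.index[shift >= 0]) & induced_ifng_ids
        calls[f"persistent_{treatment}"] = calls["feature_id"].isin(
            persistent_ids
        ) & calls["induced_ifng"]

    summary: dict = {
        "n_features": int(matrix.n_features),
        "n_induced_ifng": int(calls["induced_ifng"].sum()),
        "n_induced_lps": int(calls["induced_lps"].sum()),
        "n_induced_lps_rux": int(calls["induced_lps_rux"].sum()),
        "n_shared": int(calls["shared"].sum()),
    }
    for treatment in arm_conditions:
        if calls["induced_ifng"].any():
            summary[f"persistence_fraction_{treatment}"] = persistence_fraction(
                calls, treatment
            )

    # washout shift of IFNγ-induced and shared peaks (media arm)
    means = condition_mean_cpm(matrix, design)
    calls["washout_l2fc"] = np.nan
    if "ifng_wash_media" in means.columns:
        for name, ids in (("ifng_induced", induced_ifng_ids), ("shared", shared_ids)):
            if not ids:
                continue
            idx = sorted(ids)
            l2fc, mean_l2fc, p = washout_shift(
                means.loc[idx, "ifng_8h"], means.loc[idx, "ifng_wash_media"], prior
            )
            summary[f"washout_mean_l2fc_{name}"] = mean_l2fc
            summary[f"washout_wilcoxon_p_{name}"] = p
            if name == "ifng_induced":
                calls.loc[calls["feature_id"].isin(ids), "washout_l2fc"] = (
                    pd.Series(l2fc, index=idx)
                    .reindex(calls.loc[calls["feature_id"].isin(ids), "feature_id"])
                    .to_numpy()
                )
        if shared_ids and "lps_wash_media" in means.columns:
            idx = sorted(shared_ids)
            _, mean_l2fc, p = washout_shift(
                means.loc[idx, "lps_8h"], means.loc[idx, "lps_wash_media"], prior
            )
            summary["washout_mean_l2fc_shared_lps"] = mean_l2fc
            summary["washout_wilcoxon_p_shared_lps"] = p

    cluster_table = None
    calls["cluster_id"] = -1
    calls["cluster_label"] = "n/a"
    if len(induced_ifng_ids) >= cluster_k and "ifng_wash_media" in means.columns:
        idx = sorted(induced_ifng_ids)
        if cluster_columns == "replicates":
            cpm = (
                matrix.to_frame()
                .div(matrix.library_sizes, axis=1)
                .mul(1e6)
            )
            cols: list[str] = []
            groups: dict[str, list[int]] = {"unstim": [], "ifng_8h": [], "wash": []}
            for cond, key in (
                ("unstim", "unstim"),
                ("ifng_8h", "ifng_8h"),
                ("ifng_wash_media", "wash"),
            ):
                for s in design.samples_in(cond):
                    groups[key].append(len(cols))
                    cols.append(s)
            values = np.log2(cpm.loc[idx, cols].to_numpy() + prior)
            wash_cols, stim_cols = groups["wash"], groups["ifng_8h"]
        else:  # condition means
            cols = ["unstim", "ifng_8h", "ifng_wash_media"]
            values = np.log2(means.loc[idx, cols].to_numpy() + prior)
            wash_cols, stim_cols = [2], [1]
        cluster_table, _ = _cluster.cluster_behaviors(
            values,
            idx,
            washout_cols=wash_cols,
            stim_cols=stim_cols,
            k=cluster_k,
            seed=cluster_seed,
            n_restarts=cluster_restarts,
        )
        cmap_id = cluster_table.set_index("feature_id")["cluster_id"]
        cmap_label = cluster_table.set_index("feature_id")["cluster_label"]
        mask = calls["feature_id"].isin(cmap_id.index)
        calls.loc[mask, "cluster_id"] = calls.loc[mask, "feature_id"].map(cmap_id)
        calls.loc[mask, "cluster_label"] = calls.loc[mask, "feature_id"].map(cmap_label)

    metadata = {
        "l2fc_cutoff": l2fc_cutoff,
        "fdr_cutoff": fdr_cutoff,
        "prior_cpm": prior,
        "persistence_reference": persistence_reference,
        "abundance_filter": apply_abundance_filter,
        "cluster_k": cluster_k,
        "cluster_seed": cluster_seed,
        "cluster_restarts": cluster_restarts,
        "cluster_columns": cluster_columns,
    }
    return PeakMemoryResult(
        calls=calls,
        contrasts=contrasts,
        summary=summary,
        cluster_table=cluster_table,
        metadata=metadata,
    )
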