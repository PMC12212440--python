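"""Gene-level memory classifiers: ISG persistence, potentiation, tolerance.

Two analyses operate on RNA-seq CPM summaries (replicate means per
condition):

1. **ISG persistence** — genes induced at least 5-fold by 8 h of IFNγ are
   tiered by the fraction of their 8 h expression retained 88 h after
   washout: >= 90% (``ge90``), 20–90% (``mid20_90``), or < 20% (``lt20``),
   separately for media and ruxolitinib washout arms.

2. **Restimulation time course** — macrophages pretreated with IFNγ or
   vehicle (PBS) are restimulated with LPS and sampled at 1, 3, 6 and 12 h
   (0 h = pre-LPS, 88 h post-washout). A gene is *LPS-inducible* if its
   CPM rises at least 5-fold over its own 0 h level at any post-LPS
   timepoint (4-fold in the ruxolitinib arm); *potentiated* if the
   IFNγ-arm / PBS-arm CPM ratio is >= 2 at two contiguous post-LPS
   timepoints; *tolerized* if that ratio is <= 0.5 at two contiguous
   timepoints while LPS induction is confirmed (>= 4-fold) under JAK
   blockade. The pre-LPS set point is ``elevated`` when the 0 h IFNγ-vs-PBS
   log2 fold change is >= 0.5, else ``unchanged``.

All ratios use a shared CPM pseudo-count and inclusive ("at least")
thresholds. 0 h is reserved for the basal classifier and never counts
toward contiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diff import DEFAULT_PRIOR_CPM, condition_mean_cpm, log2_fold_change
from .matrix import CountMatrix, SampleDesign

__all__ = [
    "GeneTimeCourse",
    "call_ifng_induced_gene",
    "persistence_tier",
    "call_lps_inducible",
    "call_potentiated",
    "classify_basal",
    "call_tolerized",
    "classify_genes",
    "GeneMemoryResult",
    "PERSISTENCE_TIERS",
]

PERSISTENCE_TIERS = ("ge90", "mid20_90", "lt20", "not_induced")


@dataclass
class GeneTimeCourse:
    """Replicate-mean CPM of one gene along one arm's LPS time course."""

    gene_id: str
    arm: str  # e.g. "ifng_media", "pbs_media", "ifng_rux"
    cpm_by_time: dict[int, float]

    def __post_init__(self) -> None:
        self.cpm_by_time = {int(t): float(v) for t, v in self.cpm_by_time.items()}
        if 0 not in self.cpm_by_time:
            raise ValueError(f"time course for {self.gene_id!r} lacks the 0 h point")
        if any(v < 0 for v in self.cpm_by_time.values()):
            raise ValueError("CPM values must be non-negative")

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.cpm_by_time)

    @property
    def post_lps_timepoints(self) -> list[int]:
        return [t for t in self.timepoints if t > 0]


def call_ifng_induced_gene(
    cpm_ifng_8h: float,
    cpm_ref: float,
    fold_cutoff: float = 5.0,
    prior: float = DEFAULT_PRIOR_CPM,
) -> bool:
    """Gene induced at least ``fold_cutoff``-fold by 8 h IFNγ (inclusive)."""
    return (cpm_ifng_8h + prior) / (cpm_ref + prior) >= fold_cutoff


def persistence_tier(
    cpm_8h: float, cpm_washout: float, prior: float = DEFAULT_PRIOR_CPM
) -> str:
    """Tier an induced gene by post-washout retention of its 8 h expression.

    Retention is ``(cpm_washout + prior) / (cpm_8h + prior)``; ``ge90`` at
    >= 0.9, ``mid20_90`` in [0.2, 0.9), else ``lt20``. Only meaningful for
    genes already called IFNγ-induced — callers must gate on that (see
    :func:`classify_genes`), since retention of an uninduced gene is
    noise around 1.
    """
    retained = (cpm_washout + prior) / (cpm_8h + prior)
    if retained >= 0.9:
        return "ge90"
    if retained >= 0.2:
        return "mid20_90"
    return "lt20"


def call_lps_inducible(
    tc: GeneTimeCourse, fold_cutoff: float = 5.0, prior: float = DEFAULT_PRIOR_CPM
) -> bool:
    """Max fold over the arm's own 0 h across post-LPS timepoints >= cutoff."""
    post = tc.post_lps_timepoints
    if not post:
        raise ValueError(f"time course for {tc.gene_id!r} has no post-LPS timepoints")
    c0 = tc.cpm_by_time[0]
    folds = [(tc.cpm_by_time[t] + prior) / (c0 + prior) for t in post]
    return max(folds) >= fold_cutoff


def _contiguous_ratio_hit(
    tc_ifng: GeneTimeCourse,
    tc_pbs: GeneTimeCourse,
    prior: float,
    threshold: float,
    direction: str,
) -> bool:
    post = tc_ifng.post_lps_timepoints
    if post != tc_pbs.post_lps_timepoints:
        raise ValueError(
            f"arms for {tc_ifng.gene_id!r} have mismatched timepoints: "
            f"{post} vs {tc_pbs.post_lps_timepoints}"
        )
    ratios = [
        (tc_ifng.cpm_by_time[t] + prior) / (tc_pbs.cpm_by_time[t] + prior)
        for t in post
    ]
    if direction == "ge":
        hits = [r >= threshold for r in ratios]
    else:
        hits = [r <= threshold for r in ratios]
    return any(a and b for a, b in zip(hits, hits[1:]))


def call_potentiated(
    tc_ifng: GeneTimeCourse,
    tc_pbs: GeneTimeCourse,
    ratio_cutoff: float = 2.0,
    prior: float = DEFAULT_PRIOR_CPM,
) -> bool:
    """IFNγ/PBS CPM ratio >= cutoff at two contiguous post-LPS timepoints.

    Inducibility is a separate gate — see :func:`classify_genes`.
    """
    return _contiguous_ratio_hit(tc_ifng, tc_pbs, prior, ratio_cutoff, "ge")


def classify_basal(
    tc_ifng: GeneTimeCourse,
    tc_pbs: GeneTimeCourse,
    l2fc_cutoff: float = 0.5,
    prior: float = DEFAULT_PRIOR_CPM,
) -> str:
    """Pre-LPS set point: ``unchanged`` iff 0 h l2fc (IFNγ vs PBS) < cutoff."""
    l2fc = float(
        log2_fold_change(tc_ifng.cpm_by_time[0], tc_pbs.cpm_by_time[0], prior)
    )
    return "unchanged" if l2fc < l2fc_cutoff else "elevated"


def call_tolerized(
    tc_ifng: GeneTimeCourse,
    tc_pbs: GeneTimeCourse,
    tc_rux: GeneTimeCourse,
    ratio_cutoff: float = 0.5,
    rux_fold_cutoff: float = 4.0,
    prior: float = DEFAULT_PRIOR_CPM,
) -> bool:
    """Two-fold contiguous suppression plus confirmed induction under JAK blockade.

    Tolerized iff the IFNγ/PBS ratio is <= ``ratio_cutoff`` at two
    contiguous post-LPS timepoints AND the ruxolitinib-arm time course is
    LPS-inducible at ``rux_fold_cutoff``.
    """
    if tc_rux is None:
        raise ValueError("tolerance requires the ruxolitinib-arm time course")
    suppressed = _contiguous_ratio_hit(tc_ifng, tc_pbs, prior, ratio_cutoff, "le")
    return suppressed and call_lps_inducible(tc_rux, rux_fold_cutoff, prior)


@dataclass
class GeneMemoryResult:
    calls: pd.DataFrame = field(repr=False)
    summary: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def _tc(mean_cpm: pd.DataFrame, gene: str, pre: str, tr: str, times: list[int]) -> GeneTimeCourse:
    return GeneTimeCourse(
        gene_id=gene,
        arm=f"{pre}_{tr}",
        cpm_by_time={t: float(mean_cpm.at[gene, f"{pre}_{tr}_{t}h"]) for t in times},
    )


def classify_genes(
    matrix: CountMatrix,
    design: SampleDesign,
    criteria: str = "media",
    fold_cutoff_media: float = 5.0,
    fold_cutoff_rux: float = 4.0,
    ratio_cutoff: float = 2.0,
    basal_l2fc_cutoff: float = 0.5,
    isg_fold_cutoff: float = 5.0,
    prior: float = DEFAULT_PRIOR_CPM,
    inducible_mode: str = "either_arm",
    isg_reference: str = "vehicle_8h",
) -> GeneMemoryResult:
    """Run all gene-memory classifiers on an RNA-seq count matrix.

    ``criteria`` selects the inducibility gate for potentiation calls:
    ``"media"`` uses the 5-fold LPS-induction rule in the media arms;
    ``"rux"`` additionally requires 4-fold induction in the ruxolitinib
    arm (the JAK-blockade-compatible gene set). Tolerance always requires
    the ruxolitinib confirmation by definition. ``inducible_mode`` decides
    whether the media-arm induction may be met in either pretreatment arm
    (default) or in a specific one (``"pbs_arm"`` / ``"ifng_arm"``).

    Potentiated and tolerized are mutually exclusive by construction: a
    gene whose contiguous ratios satisfy both directions (possible only at
    disjoint timepoint pairs) is called neither and flagged ``ambiguous``.
    """
    if criteria not in ("media", "rux"):
        raise ValueError("criteria must be 'media' or 'rux'")
    if inducible_mode not in ("either_arm", "pbs_arm", "ifng_arm"):
        raise ValueError("bad inducible_mode")
    design.validate_against(matrix)
    mean_cpm = condition_mean_cpm(matrix, design)
    times = sorted(
        {
            int(c.rsplit("_", 1)[1].rstrip("h"))
            for c in mean_cpm.columns
            if c.startswith("pbs_media_")
        }
    )
    has_acute = "ifng_8h" in mean_cpm.columns and "pbs_8h" in mean_cpm.columns

    rows = []
    for gene in matrix.feature_ids:
        tc_pbs = _tc(mean_cpm, gene, "pbs", "media", times)
        tc_ifng = _tc(mean_cpm, gene, "ifng", "media", times)
        tc_rux = _tc(mean_cpm, gene, "ifng", "rux", times)

        if has_acute:
            ref = mean_cpm.at[gene, "pbs_8h"] if isg_reference == "vehicle_8h" else tc_pbs.cpm_by_time[0]
            ifng_induced = call_ifng_induced_gene(
                mean_cpm.at[gene, "ifng_8h"], ref, isg_fold_cutoff, prior
            )
            if ifng_induced:
                tier_media = persistence_tier(
                    mean_cpm.at[gene, "ifng_8h"], tc_ifng.cpm_by_time[0], prior
                )
                tier_rux = persistence_tier(
                    mean_cpm.at[gene, "ifng_8h"], tc_rux.cpm_by_time[0], prior
                )
            else:
                tier_media = tier_rux = "not_induced"
        else:
            ifng_induced = False
            tier_media = tier_rux = "not_induced"

        ind_pbs = call_lps_inducible(tc_pbs, fold_cutoff_media, prior)
        ind_ifng = call_lps_inducible(tc_ifng, fold_cutoff_media, prior)
        if inducible_mode == "either_arm":
            lps_inducible = ind_pbs or ind_ifng
        elif inducible_mode == "pbs_arm":
            lps_inducible = ind_pbs
        else:
            lps_inducible = ind_ifng
        rux_compatible = call_lps_inducible(tc_rux, fold_cutoff_rux, prior)

        gate = lps_inducible if criteria == "media" else (lps_inducible and rux_compatible)
        pot_ratio = call_potentiated(tc_ifng, tc_pbs, ratio_cutoff, prior)
        tol = call_tolerized(
            tc_ifng, tc_pbs, tc_rux, 1.0 / ratio_cutoff, fold_cutoff_rux, prior
        )
        potentiated = bool(gate and pot_ratio)
        tolerized = bool(lps_inducible and tol)
        ambiguous = potentiated and tolerized
        if ambiguous:
            potentiated = tolerized = False

        basal = classify_basal(tc_ifng, tc_pbs, basal_l2fc_cutoff, prior) if lps_inducible else "n/a"

        rows.append(
            dict(
                gene_id=gene,
                ifng_induced_8h=ifng_induced,
                persistence_tier=tier_media,
                persistence_tier_rux=tier_rux,
                lps_inducible=lps_inducible,
                rux_compatible_inducible=rux_compatible,
                potentiated=potentiated,
                tolerized=tolerized,
                ambiguous=ambiguous,
                basal_class=basal,
            )
        )

    calls = pd.DataFrame(rows)
    summary = {
        "criteria": criteria,
        "n_genes": int(len(calls)),
        "n_ifng_induced": int(calls["ifng_induced_8h"].sum()),
        "n_lps_inducible": int(calls["lps_inducible"].sum()),
        "n_rux_compatible": int(calls["rux_compatible_inducible"].sum()),
        "n_potentiated": int(calls["potentiated"].sum()),
        "n_tolerized": int(calls["tolerized"].sum()),
        "tier_counts_media": calls.loc[calls["ifng_induced_8h"], "persistence_tier"]
        .value_counts()
        .to_dict(),
        "tier_counts_rux": calls.loc[calls["ifng_induced_8h"], "persistence_tier_rux"]
        .value_counts()
        .to_dict(),
        "basal_counts": calls.loc[calls["potentiated"], "basal_class"]
        .value_counts()
        .to_dict(),
    }
    metadata = {
        "criteria": criteria,
        "fold_cutoff_media": fold_cutoff_media,
        "fold_cutoff_rux": fold_cutoff_rux,
        "ratio_cutoff": ratio_cutoff,
        "basal_l2fc_cutoff": basal_l2fc_cutoff,
        "isg_fold_cutoff": isg_fold_cutoff,
        "prior_cpm": prior,
        "inducible_mode": inducible_mode,
        "isg_reference": isg_reference,
    }
    return GeneMemoryResult(calls=calls, summary=summary, metadata=metadata)
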