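"""Seeded negative-binomial count simulator with ground-truth archetypes.

The generator emulates the two experimental designs the analysis modules
operate on:

* **Peak mode** — H3K4me1 CUT&Tag / ATAC consensus peaks quantified in
  unstimulated macrophages, after 8 h of acute stimulation (IFNγ, LPS, or
  LPS + ruxolitinib), and 88 h after stimulus washout under three
  post-washout treatments (plain media, anti-IFNγ neutralizing antibody,
  ruxolitinib). Peak archetypes: ``unresponsive``, ``lps_specific``
  (JAK-independent), ``shared_jak`` (induced by both stimuli, ruxolitinib-
  sensitive), and ``ifng_specific``. Every IFNγ-induced peak carries a
  washout behavior (``persist``, ``decay``, ``augment``) realized as the
  fraction of the acute log2 effect retained after washout, further scaled
  by a per-treatment retention multiplier.

* **Gene mode** — an LPS restimulation time course (0, 1, 3, 6, 12 h) in
  macrophages pretreated with IFNγ or vehicle (PBS) and cultured through
  washout in plain media or ruxolitinib, plus acute 8 h IFNγ/vehicle
  libraries for interferon-stimulated-gene (ISG) calling. Gene archetypes:
  ``housekeeping``, ``isg_persistent``, ``isg_transient``,
  ``potentiated_elevated_basal``, ``potentiated_unchanged_basal``,
  ``tolerized``, and ``jak_dependent_induction``.

Counts are negative-binomial with variance ``mu + phi * mu**2``; per-feature
baseline abundance (CPM) and dispersion ``phi`` are log-normal. Library
sizes represent total aligned reads per library, so the simulated features
account for only a small fraction of each library — as consensus peaks or a
protein-coding gene panel do in real data.

Every draw flows from a single :class:`numpy.random.Generator` seeded from
``SimConfig.seed``, so identical configurations yield bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .matrix import CountMatrix, SampleDesign

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimConfigError",
    "generate_truth",
    "simulate_counts",
    "simulate",
    "sample_nb_counts",
    "PEAK_ARCHETYPES",
    "GENE_ARCHETYPES",
    "PEAK_CONDITIONS",
    "gene_conditions",
]


class SimConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


PEAK_ARCHETYPES = ("unresponsive", "lps_specific", "shared_jak", "ifng_specific")
GENE_ARCHETYPES = (
    "housekeeping",
    "isg_persistent",
    "isg_transient",
    "potentiated_elevated_basal",
    "potentiated_unchanged_basal",
    "tolerized",
    "jak_dependent_induction",
)

#: condition labels of the peak design, in sample-sheet order
PEAK_CONDITIONS = (
    "unstim",
    "ifng_8h",
    "lps_8h",
    "lps_rux_8h",
    "ifng_wash_media",
    "ifng_wash_ab",
    "ifng_wash_rux",
    "lps_wash_media",
)

_PEAK_CONDITION_META = {
    "unstim": ("unstim", 0, "none"),
    "ifng_8h": ("ifng", 8, "none"),
    "lps_8h": ("lps", 8, "none"),
    "lps_rux_8h": ("lps_rux", 8, "none"),
    "ifng_wash_media": ("ifng", 96, "media"),
    "ifng_wash_ab": ("ifng", 96, "anti_ifng_ab"),
    "ifng_wash_rux": ("ifng", 96, "ruxolitinib"),
    "lps_wash_media": ("lps", 96, "media"),
}

#: post-washout treatment -> fraction of the retained effect that survives
DEFAULT_TREATMENT_EFFECTS = {"media": 1.0, "anti_ifng_ab": 0.45, "ruxolitinib": 0.15}

#: washout behavior -> fraction of the acute log2 effect retained in media
DEFAULT_WASHOUT_RETENTION = {"persist": 1.0, "decay": 0.0, "augment": 1.5}

DEFAULT_BEHAVIOR_PROPORTIONS = {"persist": 0.5, "decay": 0.3, "augment": 0.2}

DEFAULT_PEAK_PROPORTIONS = {
    "unresponsive": 0.55,
    "lps_specific": 0.15,
    "shared_jak": 0.15,
    "ifng_specific": 0.15,
}

DEFAULT_GENE_PROPORTIONS = {
    "housekeeping": 0.55,
    "isg_persistent": 0.08,
    "isg_transient": 0.07,
    "potentiated_elevated_basal": 0.08,
    "potentiated_unchanged_basal": 0.07,
    "tolerized": 0.07,
    "jak_dependent_induction": 0.08,
}

#: fold induction over naive 0 h at each post-LPS timepoint (hours)
DEFAULT_LPS_FOLD_PROFILE = {1: 3.0, 3: 8.0, 6: 10.0, 12: 6.0}


def gene_conditions(timepoints_h: tuple[int, ...] = (0, 1, 3, 6, 12)) -> list[str]:
    """All condition labels of the gene design, in sample-sheet order."""
    conds = ["pbs_8h", "ifng_8h"]
    for pre in ("pbs", "ifng"):
        for tr in ("media", "rux"):
            for t in timepoints_h:
                conds.append(f"{pre}_{tr}_{t}h")
    return conds


@dataclass
class SimConfig:
    """Configuration of one simulated experiment.

    ``kind`` selects the peak or gene design. Proportions must sum to 1
    (tolerance 1e-9) over the archetypes of the selected kind. Effect sizes
    are log2 units; dispersions and CPMs are drawn log-normal with the
    given log-scale moments.
    """

    kind: str = "peaks"  # "peaks" | "genes"
    n_features: int = 2000
    archetype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PEAK_PROPORTIONS)
    )
    base_cpm_log_mean: float = math.log(20.0)
    base_cpm_log_sd: float = 1.0
    dispersion_log_mean: float = math.log(0.05)
    dispersion_log_sd: float = 0.5
    induced_l2fc_mean: float = 3.5
    induced_l2fc_sd: float = 0.5
    washout_retention: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WASHOUT_RETENTION)
    )
    behavior_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR_PROPORTIONS)
    )
    treatment_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_EFFECTS)
    )
    n_replicates: int = 2
    library_size_mean: float = 5e6
    library_size_cv: float = 0.2
    seed: int = 0
    timepoints_h: tuple[int, ...] = (0, 8, 96)
    # gene-mode shape parameters (piecewise-constant per timepoint)
    lps_fold_profile: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LPS_FOLD_PROFILE)
    )
    isg_fold: float = 10.0
    isg_retention: dict[str, float] = field(
        default_factory=lambda: {"isg_persistent": 0.95, "isg_transient": 0.25}
    )
    isg_rux_retention: float = 0.02
    potentiation_factor: float = 3.0
    tolerization_factor: float = 0.3
    basal_elevation_l2fc: float = 1.5
    jak_dependent_rux_cap: float = 1.5

    @classmethod
    def peaks_default(cls, **overrides) -> "SimConfig":
        return replace(cls(kind="peaks", timepoints_h=(0, 8, 96)), **overrides)

    @classmethod
    def genes_default(cls, **overrides) -> "SimConfig":
        cfg = cls(
            kind="genes",
            archetype_proportions=dict(DEFAULT_GENE_PROPORTIONS),
            timepoints_h=(0, 1, 3, 6, 12),
        )
        return replace(cfg, **overrides)

    def validate(self) -> None:
        if self.kind not in ("peaks", "genes"):
            raise SimConfigError(f"kind must be 'peaks' or 'genes', got {self.kind!r}")
        if self.n_features < 1:
            raise SimConfigError("n_features must be >= 1")
        allowed = PEAK_ARCHETYPES if self.kind == "peaks" else GENE_ARCHETYPES
        unknown = set(self.archetype_proportions) - set(allowed)
        if unknown:
            raise SimConfigError(
                f"archetype_proportions has unknown archetypes for kind={self.kind!r}: "
                f"{sorted(unknown)}"
            )
        total = sum(self.archetype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise SimConfigError(
                f"archetype_proportions must sum to 1 (got {total!r})"
            )
        if any(p < 0 for p in self.archetype_proportions.values()):
            raise SimConfigError("archetype_proportions must be non-negative")
        btotal = sum(self.behavior_proportions.values())
        if abs(btotal - 1.0) > 1e-9:
            raise SimConfigError(f"behavior_proportions must sum to 1 (got {btotal!r})")
        if self.dispersion_log_sd < 0 or self.base_cpm_log_sd < 0:
            raise SimConfigError("log_sd fields must be >= 0")
        if self.library_size_mean <= 0:
            raise SimConfigError("library_size_mean must be > 0")
        if self.n_replicates < 1:
            raise SimConfigError("n_replicates must be >= 1")
        if list(self.timepoints_h) != sorted(set(self.timepoints_h)):
            raise SimConfigError("timepoints_h must be strictly increasing")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["timepoints_h"] = list(self.timepoints_h)
        return d


@dataclass
class SimTruth:
    """Ground truth for one simulated feature.

    ``l2fc_by_condition`` maps condition labels to the true log2 fold
    change of the feature's concentration relative to the naive baseline
    (``unstim`` for peaks, the PBS/media 0 h arm for genes); conditions not
    listed are at baseline (l2fc 0).
    """

    feature_id: str
    archetype: str
    washout_behavior: str  # "persist" | "decay" | "augment" | "na"
    base_cpm: float
    dispersion: float
    l2fc_by_condition: dict[str, float] = field(default_factory=dict)

    def true_l2fc(self, condition: str) -> float:
        return self.l2fc_by_condition.get(condition, 0.0)


def _archetype_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder rounding so counts sum exactly to ``n``."""
    items = list(proportions.items())
    raw = [p * n for _, p in items]
    counts = [int(math.floor(r)) for r in raw]
    short = n - sum(counts)
    remainders = sorted(
        range(len(items)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in remainders[:short]:
        counts[i] += 1
    return {name: c for (name, _), c in zip(items, counts)}


def _draw_induced_l2fc(rng: np.random.Generator, cfg: SimConfig) -> float:
    # floor keeps "induced" features genuinely induced even in wide-sd configs
    return max(0.25, float(rng.normal(cfg.induced_l2fc_mean, cfg.induced_l2fc_sd)))


def _peak_effects(
    rng: np.random.Generator, cfg: SimConfig, archetype: str, behavior: str
) -> dict[str, float]:
    eff: dict[str, float] = {}
    if archetype == "unresponsive":
        return eff
    L = _draw_induced_l2fc(rng, cfg)
    retention = cfg.washout_retention.get(behavior, 0.0)
    if archetype == "lps_specific":
        # TLR-driven, JAK-independent: induced with and without ruxolitinib,
        # and reverting toward baseline after washout
        eff["lps_8h"] = L
        eff["lps_rux_8h"] = L
        eff["lps_wash_media"] = 0.0
        return eff
    if archetype == "shared_jak":
        eff["ifng_8h"] = L
        eff["lps_8h"] = L
        eff["lps_wash_media"] = 0.0
    elif archetype == "ifng_specific":
        eff["ifng_8h"] = L
    for treatment, mult in cfg.treatment_effects.items():
        cond = {
            "media": "ifng_wash_media",
            "anti_ifng_ab": "ifng_wash_ab",
            "ruxolitinib": "ifng_wash_rux",
        }[treatment]
        eff[cond] = L * retention * mult
    return eff


def _gene_effects(
    rng: np.random.Generator, cfg: SimConfig, archetype: str
) -> dict[str, float]:
    prof = {0: 1.0, **{int(t): float(f) for t, f in cfg.lps_fold_profile.items()}}
    times = [int(t) for t in cfg.timepoints_h]
    post = [t for t in times if t > 0]

    def l2(x: float) -> float:
        return math.log2(max(x, 1e-12))

    fold: dict[str, float] = {}
    if archetype == "housekeeping":
        return {}

    if archetype in ("isg_persistent", "isg_transient"):
        F = cfg.isg_fold
        r = cfg.isg_retention[archetype]
        fold["ifng_8h"] = F
        retained = 1.0 + (F - 1.0) * r
        retained_rux = 1.0 + (F - 1.0) * cfg.isg_rux_retention
        for t in times:
            fold[f"ifng_media_{t}h"] = retained  # not LPS-responsive
            fold[f"ifng_rux_{t}h"] = retained_rux
        return {c: l2(v) for c, v in fold.items()}

    # LPS-inducible archetypes share the naive response shape in PBS arms
    for pre in ("pbs",):
        for tr in ("media", "rux"):
            for t in times:
                f = prof.get(t, 1.0)
                if archetype == "jak_dependent_induction" and tr == "rux":
                    f = min(f, cfg.jak_dependent_rux_cap)
                fold[f"{pre}_{tr}_{t}h"] = f

    P = cfg.potentiation_factor
    B = 2.0 ** cfg.basal_elevation_l2fc
    if archetype == "potentiated_elevated_basal":
        fold["ifng_8h"] = 6.0  # modest direct ISG-like induction
        for t in times:
            base = prof.get(t, 1.0)
            fold[f"ifng_media_{t}h"] = B if t == 0 else base * P
            fold[f"ifng_rux_{t}h"] = base  # JAK blockade erases the memory
    elif archetype == "potentiated_unchanged_basal":
        late = post[-2:]  # potentiation only at the two latest timepoints
        for t in times:
            base = prof.get(t, 1.0)
            fold[f"ifng_media_{t}h"] = base * (P if t in late else 1.0)
            fold[f"ifng_rux_{t}h"] = base
    elif archetype == "tolerized":
        early = post[:2]  # suppression at the two earliest post-LPS timepoints
        T = cfg.tolerization_factor
        for t in times:
            base = prof.get(t, 1.0)
            fold[f"ifng_media_{t}h"] = base * (T if t in early else 1.0)
            fold[f"ifng_rux_{t}h"] = base
    elif archetype == "jak_dependent_induction":
        for t in times:
            base = prof.get(t, 1.0)
            fold[f"ifng_media_{t}h"] = base
            fold[f"ifng_rux_{t}h"] = min(base, cfg.jak_dependent_rux_cap)
    else:  # pragma: no cover - guarded by validate()
        raise SimConfigError(f"unknown gene archetype {archetype!r}")
    return {c: l2(v) for c, v in fold.items()}


def generate_truth(config: SimConfig) -> list[SimTruth]:
    """Draw per-feature archetypes, abundances, dispersions and effects.

    Deterministic given ``config.seed``; archetype counts equal the
    largest-remainder rounding of ``proportions * n_features``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = _archetype_counts(config.archetype_proportions, config.n_features)
    behaviors = list(config.behavior_proportions)
    bprobs = np.array([config.behavior_proportions[b] for b in behaviors], dtype=float)
    bprobs = bprobs / bprobs.sum()

    prefix = "peak" if config.kind == "peaks" else "gene"
    truths: list[SimTruth] = []
    idx = 0
    for archetype, n_arch in counts.items():
        for _ in range(n_arch):
            base_cpm = float(
                rng.lognormal(config.base_cpm_log_mean, config.base_cpm_log_sd)
            )
            phi = float(
                rng.lognormal(config.dispersion_log_mean, config.dispersion_log_sd)
            )
            if config.kind == "peaks":
                if archetype in ("shared_jak", "ifng_specific"):
                    behavior = str(rng.choice(behaviors, p=bprobs))
                elif archetype == "lps_specific":
                    behavior = "decay"
                else:
                    behavior = "na"
                effects = _peak_effects(rng, config, archetype, behavior)
            else:
                behavior = "na"
                effects = _gene_effects(rng, config, archetype)
            truths.append(
                SimTruth(
                    feature_id=f"{prefix}_{idx:05d}",
                    archetype=archetype,
                    washout_behavior=behavior,
                    base_cpm=base_cpm,
                    dispersion=phi,
                    l2fc_by_condition=effects,
                )
            )
            idx += 1
    # deterministic shuffle so archetypes are not ordered blocks
    order = rng.permutation(len(truths))
    truths = [truths[i] for i in order]
    for i, t in enumerate(truths):
        t.feature_id = f"{prefix}_{i:05d}"
    return truths


def sample_nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray
) -> np.ndarray:
    """Negative-binomial draws with variance ``mean + dispersion * mean**2``.

    ``dispersion`` below 1e-10 falls back to Poisson; zero means yield
    exact zeros.
    """
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    pois = pos & (phi < 1e-10)
    nb = pos & ~pois
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mean[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def _build_design(config: SimConfig) -> tuple[pd.DataFrame, list[str]]:
    rows = []
    if config.kind == "peaks":
        conditions = list(PEAK_CONDITIONS)
        for cond in conditions:
            stim, t, wash = _PEAK_CONDITION_META[cond]
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    dict(
                        sample_id=f"{cond}_r{rep}",
                        assay="h3k4me1",
                        condition=cond,
                        stimulus=stim,
                        time_h=t,
                        washout_treatment=wash,
                        pretreatment="none",
                        replicate=rep,
                    )
                )
    else:
        conditions = gene_conditions(tuple(int(t) for t in config.timepoints_h))
        for cond in conditions:
            if cond in ("pbs_8h", "ifng_8h"):
                stim = cond.split("_")[0]
                meta = dict(stimulus=stim, time_h=8, washout_treatment="none", pretreatment="none")
            else:
                pre, tr, th = cond.rsplit("_", 2)
                t = int(th.rstrip("h"))
                meta = dict(
                    stimulus="lps" if t > 0 else "pbs",
                    time_h=t,
                    washout_treatment={"media": "media", "rux": "ruxolitinib"}[tr],
                    pretreatment=pre,
                )
            for rep in range(1, config.n_replicates + 1):
                rows.append(dict(sample_id=f"{cond}_r{rep}", assay="rnaseq", condition=cond, replicate=rep, **meta))
    return pd.DataFrame(rows), conditions


def _peak_coords(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic non-overlapping peak intervals on a small chromosome set."""
    chroms = np.array([f"chr{c}" for c in rng.integers(1, 23, size=n)])
    starts = rng.integers(1_000, 100_000_000, size=n)
    widths = rng.integers(200, 2_000, size=n)
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + widths})


def simulate_counts(
    truth: list[SimTruth], config: SimConfig
) -> tuple[CountMatrix, SampleDesign]:
    """Draw the count matrix and sample sheet implied by a truth list.

    Counts for feature *f* in sample *s* are NB with mean
    ``library_size[s] * base_cpm[f] * 2**l2fc[f, condition(s)] / 1e6`` and
    the feature's dispersion. Seeded from ``config.seed`` (offset so truth
    generation and count sampling use distinct streams).
    """
    config.validate()
    if len(truth) != config.n_features:
        raise SimConfigError(
            f"truth has {len(truth)} features but config.n_features={config.n_features}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    design_df, conditions = _build_design(config)
    n_samples = len(design_df)

    sigma = math.sqrt(math.log(1.0 + config.library_size_cv**2))
    lib = rng.lognormal(math.log(config.library_size_mean) - sigma**2 / 2, sigma, n_samples)

    base = np.array([t.base_cpm for t in truth])
    phi = np.array([t.dispersion for t in truth])
    l2fc = np.zeros((len(truth), len(conditions)))
    for j, cond in enumerate(conditions):
        l2fc[:, j] = [t.true_l2fc(cond) for t in truth]
    cond_index = {c: j for j, c in enumerate(conditions)}
    col_cond = design_df["condition"].map(cond_index).to_numpy()

    mean = base[:, None] * (2.0 ** l2fc[:, col_cond]) * (lib[None, :] / 1e6)
    counts = sample_nb_counts(rng, mean, phi[:, None])

    coords = _peak_coords(len(truth), rng) if config.kind == "peaks" else None
    design_df["library_size"] = np.round(lib).astype(np.int64)
    matrix = CountMatrix(
        counts=counts,
        feature_ids=[t.feature_id for t in truth],
        sample_ids=list(design_df["sample_id"]),
        coords=coords,
        library_sizes=design_df["library_size"].to_numpy(dtype=float),
    )
    return matrix, SampleDesign(design_df)


def simulate(config: SimConfig) -> tuple[CountMatrix, SampleDesign, list[SimTruth]]:
    """Convenience wrapper: truth + counts + design in one call."""
    truth = generate_truth(config)
    matrix, design = simulate_counts(truth, config)
    return matrix, design, truth


def truth_to_frame(truth: list[SimTruth]) -> pd.DataFrame:
    """Flatten a truth list to a table (effects serialized as JSON)."""
    import json

    return pd.DataFrame(
        {
            "feature_id": [t.feature_id for t in truth],
            "archetype": [t.archetype for t in truth],
            "washout_behavior": [t.washout_behavior for t in truth],
            "base_cpm": [t.base_cpm for t in truth],
            "dispersion": [t.dispersion for t in truth],
            "l2fc_by_condition": [
                json.dumps(t.l2fc_by_condition, sort_keys=True) for t in truth
            ],
        }
    )


def truth_from_frame(df: pd.DataFrame) -> list[SimTruth]:
    import json

    return [
        SimTruth(
            feature_id=row.feature_id,
            archetype=row.archetype,
            washout_behavior=row.washout_behavior,
            base_cpm=float(row.base_cpm),
            dispersion=float(row.dispersion),
            l2fc_by_condition=json.loads(row.l2fc_by_condition),
        )
        for row in df.itertuples(index=False)
    ]
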