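"""Synthetic RPE passage-series data with planted, donor-consistent effects.

The generator reproduces the structure of a serial-passage wound-stimulus
experiment on primary retinal pigmented epithelial (RPE) cultures: three
donors, a minimally passaged arm (P0) and a repeatedly passaged arm (P5)
profiled at 3, 16, 32 and 64 days post-plating on two-color arrays, plus an
RNA-seq arm at day 32 comparing P0, untreated P4 and TGFβ-inhibitor-treated
P4 cultures. Genes fall into classes with planted passage effects:

* ``rpe`` — differentiation/signature genes lost with passage (down in P5),
* ``wound`` — wound-response genes gained with passage (up in P5),
* ``cell_cycle`` — proliferation genes, lower in late-passage cells,
* ``housekeeping`` — stable, high expression, no effect,
* ``null`` — no passage effect.

Donor effects are random gene-level intercepts drawn once per donor, so
intra-donor fold changes cancel them while inter-donor comparisons do not —
the property the downstream donor-consistency DE criterion and its
empirical inter-donor null both rely on.

Array intensities are additive background plus a log-normal signal
(``raw = b + 2**(level + probe offset + technical noise)``); negative-control
probes carry background only, a block of probes is replicated 10x, and some
genes carry multiple unique probes. RNA-seq counts are negative-binomial
around library-size-scaled expected proportions. The treated arm moves each
rescued gene's expected log2 level fully back to its P0 value
(``level_treated = level_untreated + r * (level_P0 - level_untreated)`` with
r = 1 for rescued genes, 0 otherwise), which makes the ground truth of the
recovery statistic exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GENE_CLASSES = ("rpe", "wound", "cell_cycle", "housekeeping", "null")

#: planted direction of the P5-vs-P0 effect for each class
CLASS_SIGN = {"rpe": -1.0, "wound": +1.0, "cell_cycle": -1.0,
              "housekeeping": 0.0, "null": 0.0}


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic passage-series experiment.

    Defaults mirror the study design being emulated; see ``docs/methods.md``
    for the rationale behind each value.
    """

    n_donors: int = 3
    time_points_days: tuple[int, ...] = (3, 16, 32, 64)
    passages: tuple[str, ...] = ("P0", "P5")
    treated_passage: str = "P4"
    rnaseq_day: int = 32
    n_genes: int = 12_000
    class_fractions: Mapping[str, float] = field(default_factory=lambda: {
        "rpe": 0.15, "wound": 0.15, "cell_cycle": 0.05,
        "housekeeping": 0.05, "null": 0.60})
    effect_log2fc: Mapping[str, float] = field(default_factory=lambda: {
        "rpe": 2.0, "wound": 2.0, "cell_cycle": 2.0,
        "housekeeping": 0.0, "null": 0.0})
    rescue_fraction: float = 0.87
    donor_sd: float = 0.20
    residual_sd: float = 0.25
    technical_sd: float = 0.10
    probe_offset_sd: float = 0.50
    base_mean_log2: float = 7.0
    base_sd_log2: float = 1.5
    background_level: float = 50.0
    background_sd: float = 5.0
    nb_dispersion: float = 0.05
    lib_size: float = 2_000_000.0
    probes_per_gene_probs: tuple[float, ...] = (0.6, 0.3, 0.1)  # P(1), P(2), P(3) probes
    n_negctrl_probes: int = 300
    n_replicate_probes: int = 200
    replicate_copies: int = 10
    seed: int = 17

    def __post_init__(self):
        fracs = dict(self.class_fractions)
        unknown = set(fracs) - set(GENE_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown gene classes: {sorted(unknown)}")
        total = sum(fracs.get(c, 0.0) for c in GENE_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class_fractions sum to {total}, expected 1")
        if any(f < 0 for f in fracs.values()):
            raise ConfigurationError("class_fractions must be non-negative")
        for name in ("donor_sd", "residual_sd", "technical_sd", "probe_offset_sd",
                     "background_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.lib_size <= 0 or self.background_level <= 0:
            raise ConfigurationError("lib_size and background_level must be > 0")
        if not 0.0 <= self.rescue_fraction <= 1.0:
            raise ConfigurationError("rescue_fraction must be in [0, 1]")
        if self.n_donors < 1 or self.n_genes < 1:
            raise ConfigurationError("n_donors and n_genes must be >= 1")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _assign_classes(cfg: SimulationConfig) -> np.ndarray:
    """Deterministic per-gene class labels honouring the configured fractions."""
    counts = {c: int(round(cfg.class_fractions.get(c, 0.0) * cfg.n_genes))
              for c in GENE_CLASSES}
    # absorb rounding drift into the null class
    counts["null"] += cfg.n_genes - sum(counts.values())
    if counts["null"] < 0:
        raise ConfigurationError("class_fractions leave no room for null genes")
    labels = np.concatenate([np.repeat(c, n) for c, n in counts.items()])
    return labels


def _gene_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    classes = _assign_classes(cfg)
    n = cfg.n_genes
    genes = pd.DataFrame({
        "gene": [f"G{i:05d}" for i in range(n)],
        "class": classes,
    })
    mu = rng.normal(cfg.base_mean_log2, cfg.base_sd_log2, size=n)
    hk = classes == "housekeeping"
    mu[hk] = rng.normal(cfg.base_mean_log2 + 2.0, 0.5, size=hk.sum())
    genes["base_log2"] = mu
    sign = np.array([CLASS_SIGN[c] for c in classes])
    genes["effect_log2fc"] = sign * np.array(
        [cfg.effect_log2fc.get(c, 0.0) for c in classes])
    affected = genes["effect_log2fc"] != 0.0
    rescued = np.zeros(n, dtype=bool)
    idx = np.flatnonzero(affected.to_numpy())
    n_rescued = int(round(cfg.rescue_fraction * len(idx)))
    if n_rescued:
        rescued[rng.choice(idx, size=n_rescued, replace=False)] = True
    genes["rescued"] = rescued
    return genes


def _truth_table(cfg: SimulationConfig, genes: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, g in genes.iterrows():
        row = {"gene": g["gene"], "class": g["class"], "rescued": bool(g["rescued"])}
        for day in cfg.time_points_days:
            fc = g["effect_log2fc"]
            row[f"true_log2fc_day{day}"] = fc
            row[f"true_direction_day{day}"] = (
                "up" if fc > 0 else "down" if fc < 0 else "none")
        rows.append(row)
    return pd.DataFrame(rows)


def _sample_sheet(cfg: SimulationConfig, arms: Sequence[tuple[str, int, str]]) -> pd.DataFrame:
    """One row per donor x (passage, day, treatment) arm."""
    rows = []
    for passage, day, treatment in arms:
        density = "low" if day == 3 else "high"
        for d in range(cfg.n_donors):
            donor = f"D{d + 1}"
            suffix = "T" if treatment != "none" else ""
            rows.append({
                "sample_id": f"{donor}_{passage}{suffix}_d{day:02d}",
                "donor": donor, "passage": passage, "day": day,
                "density": density, "treatment": treatment,
            })
    return pd.DataFrame(rows)


def _expected_log2(cfg: SimulationConfig, genes: pd.DataFrame,
                   sheet: pd.DataFrame, rng: np.random.Generator,
                   donor_effects: np.ndarray) -> np.ndarray:
    """Per-gene, per-sample expected log2 level plus biological noise.

    Donor effects are supplied so array and RNA-seq arms can share them
    when generated from one config; biological residual noise is drawn
    fresh per sample.
    """
    base = genes["base_log2"].to_numpy()
    effect = genes["effect_log2fc"].to_numpy()
    rescued = genes["rescued"].to_numpy()
    donors = sorted(sheet["donor"].unique())
    donor_index = {d: i for i, d in enumerate(donors)}
    levels = np.empty((len(genes), len(sheet)))
    late = {p for p in sheet["passage"].unique() if p != "P0"}
    for j, s in enumerate(sheet.itertuples(index=False)):
        mean = base + donor_effects[:, donor_index[s.donor]]
        if s.passage in late:
            delta = effect.copy()
            if s.treatment != "none":
                # full rescue back to the P0 level for rescued genes
                delta = np.where(rescued, 0.0, delta)
            mean = mean + delta
        noise = rng.normal(0.0, cfg.residual_sd, size=len(genes)) \
            if cfg.residual_sd > 0 else 0.0
        levels[:, j] = mean + noise
    return levels


def _probe_annotation(cfg: SimulationConfig, genes: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Probe layout: multi-probe genes, a replicated block, negative controls."""
    n_probes = 1 + rng.choice(len(cfg.probes_per_gene_probs),
                              size=len(genes), p=cfg.probes_per_gene_probs)
    rows = []
    rep_genes = set(range(min(cfg.n_replicate_probes, len(genes))))
    for gi, (gene, k) in enumerate(zip(genes["gene"], n_probes)):
        for p in range(k):
            if gi in rep_genes and p == 0:
                group = f"RG{gi:04d}"
                for r in range(cfg.replicate_copies):
                    rows.append({"probe_id": f"P_{gene}_{p}_r{r:02d}",
                                 "gene_symbol": gene,
                                 "is_negative_control": False,
                                 "replicate_group": group,
                                 "_gene_index": gi})
            else:
                rows.append({"probe_id": f"P_{gene}_{p}", "gene_symbol": gene,
                             "is_negative_control": False, "replicate_group": "",
                             "_gene_index": gi})
    for i in range(cfg.n_negctrl_probes):
        rows.append({"probe_id": f"NC_{i:04d}", "gene_symbol": "",
                     "is_negative_control": True, "replicate_group": "",
                     "_gene_index": -1})
    return pd.DataFrame(rows)


def simulate_array_experiment(cfg: SimulationConfig
                              ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate probe-level two-color array intensities for the passage series.

    Returns ``(intensities, annotation, sample_sheet, truth)`` where
    ``intensities`` is probes x samples raw intensity (additive background +
    log-normal signal; negative controls carry background only),
    ``annotation`` maps probes to gene symbols / control / replicate-group
    flags, and ``truth`` is the planted per-gene ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_table(cfg, rng)
    arms = [(p, day, "none") for p in cfg.passages for day in cfg.time_points_days]
    sheet = _sample_sheet(cfg, arms)
    donor_effects = (rng.normal(0.0, cfg.donor_sd, size=(len(genes), cfg.n_donors))
                     if cfg.donor_sd > 0 else np.zeros((len(genes), cfg.n_donors)))
    levels = _expected_log2(cfg, genes, sheet, rng, donor_effects)
    annot = _probe_annotation(cfg, genes, rng)

    n_probes, n_samples = len(annot), len(sheet)
    gene_idx = annot["_gene_index"].to_numpy()
    is_nc = annot["is_negative_control"].to_numpy()
    offsets = np.where(is_nc, 0.0,
                       rng.normal(0.0, cfg.probe_offset_sd, size=n_probes))
    # replicate copies of one probe share the probe-level offset
    for group, idx in annot.groupby("replicate_group").groups.items():
        if group:
            offsets[np.asarray(idx)] = offsets[np.asarray(idx)[0]]

    tech = rng.normal(0.0, cfg.technical_sd, size=(n_probes, n_samples)) \
        if cfg.technical_sd > 0 else np.zeros((n_probes, n_samples))
    background = rng.normal(cfg.background_level, cfg.background_sd,
                            size=(n_probes, n_samples))
    background = np.clip(background, 1.0, None)
    signal = np.zeros((n_probes, n_samples))
    real = ~is_nc
    signal[real] = 2.0 ** (levels[gene_idx[real], :]
                           + offsets[real, None] + tech[real])
    raw = background + signal
    intensities = pd.DataFrame(raw, index=annot["probe_id"].to_numpy(),
                               columns=sheet["sample_id"].to_numpy())
    intensities.index.name = "probe_id"
    truth = _truth_table(cfg, genes)
    return intensities, annot.drop(columns="_gene_index"), sheet, truth


def simulate_gene_level(cfg: SimulationConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene-level linear expression for the array design, no probe layer.

    Convenience surface for studying the DE criterion itself: the same
    planted effects, donor intercepts and residual noise as the array arm,
    but returned directly as a genes x samples matrix of ``2**level``.
    Returns ``(expr, sample_sheet, truth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_table(cfg, rng)
    arms = [(p, day, "none") for p in cfg.passages for day in cfg.time_points_days]
    sheet = _sample_sheet(cfg, arms)
    donor_effects = (rng.normal(0.0, cfg.donor_sd, size=(len(genes), cfg.n_donors))
                     if cfg.donor_sd > 0 else np.zeros((len(genes), cfg.n_donors)))
    levels = _expected_log2(cfg, genes, sheet, rng, donor_effects)
    expr = pd.DataFrame(2.0 ** levels, index=genes["gene"].to_numpy(),
                        columns=sheet["sample_id"].to_numpy())
    expr.index.name = "gene"
    return expr, sheet, _truth_table(cfg, genes)


def simulate_rnaseq_experiment(cfg: SimulationConfig
                               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate gene-level RNA-seq counts for P0 / P4 / P4+inhibitor at one day.

    Counts are negative-binomial with mean ``lib_size * proportion`` where the
    per-sample proportions come from the same planted log2 levels as the array
    arm; ``nb_dispersion == 0`` gives the Poisson limit. Returns
    ``(counts, sample_sheet, truth)``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    # the gene table is drawn from the seed alone, so the array and RNA-seq
    # arms of one config share genes, classes and planted effects
    genes = _gene_table(cfg, np.random.default_rng(cfg.seed))
    arms = [("P0", cfg.rnaseq_day, "none"),
            (cfg.treated_passage, cfg.rnaseq_day, "none"),
            (cfg.treated_passage, cfg.rnaseq_day, "A-83-01")]
    sheet = _sample_sheet(cfg, arms)
    donor_effects = (rng.normal(0.0, cfg.donor_sd, size=(len(genes), cfg.n_donors))
                     if cfg.donor_sd > 0 else np.zeros((len(genes), cfg.n_donors)))
    levels = _expected_log2(cfg, genes, sheet, rng, donor_effects)
    expected = 2.0 ** levels
    proportions = expected / expected.sum(axis=0, keepdims=True)
    mean = proportions * cfg.lib_size
    if cfg.nb_dispersion > 1e-12:
        size = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mean))
    else:
        counts = rng.poisson(mean)
    count_df = pd.DataFrame(counts, index=genes["gene"].to_numpy(),
                            columns=sheet["sample_id"].to_numpy())
    count_df.index.name = "gene"
    truth = _truth_table(cfg, genes)
    return count_df, sheet, truth


def make_disease_gene_sets(truth: pd.DataFrame, seed: int = 17,
                           frac_true: float = 0.6, n_decoys: int = 150
                           ) -> dict[str, dict]:
    """Build direction-tagged disease-like gene sets from planted truth.

    Emulates externally curated disease lists (e.g. AMD up/down genes): each
    set mixes a fraction of genuinely passage-responsive genes of the matching
    direction with unaffected decoys, so directional enrichment against the
    planted DE sets is positive but not trivial.
    """
    rng = np.random.default_rng(seed)
    any_up = truth.filter(like="true_direction_").eq("up").any(axis=1)
    any_down = truth.filter(like="true_direction_").eq("down").any(axis=1)
    null_genes = truth.loc[~any_up & ~any_down, "gene"].to_numpy()
    sets = {}
    for name, mask in (("DISEASE_UP", any_up), ("DISEASE_DOWN", any_down)):
        members = truth.loc[mask, "gene"].to_numpy()
        n_true = max(1, int(round(frac_true * min(len(members), 400))))
        chosen = rng.choice(members, size=min(n_true, len(members)), replace=False)
        decoys = rng.choice(null_genes, size=min(n_decoys, len(null_genes)),
                            replace=False)
        direction = "up" if name.endswith("UP") else "down"
        sets[name] = {"description": direction,
                      "members": sorted(set(chosen) | set(decoys))}
    return sets
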