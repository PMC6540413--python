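"""Synthetic NanoString-style immune-panel cohorts.

Generates cohorts with the statistical structure the downstream analysis
assumes: a ~770-probe immune panel (730 endogenous + 40 housekeeping genes,
spike-in positive/negative controls), 24 immune cell-type and 4 response
category signatures, negative-binomial counts with per-sample library
factors, recurrence labels with planted log2 fold-change effects, a latent
per-sample T-cell level, and per-slide TIL foci counts whose mean tracks
that latent level.

Randomness is stream-split from one global seed via numpy SeedSequence:
child 0 drives panel construction, child 1 the count/label simulation and
clinical covariates, child 2 the foci simulation. Any of the three stages
can therefore be re-run independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_processing import (
    CLASS_ENDOGENOUS,
    CLASS_HOUSEKEEPING,
    CLASS_NEGATIVE,
    CLASS_POSITIVE,
    RawCountMatrix,
)
from .signatures import (
    KIND_CATEGORY,
    KIND_CELL_TYPE,
    KIND_TEFF,
    GeneSignature,
    SignatureRegistry,
)

#: the 24 immune cell types annotated on the nCounter immune profiling panel
CELL_TYPES = (
    "aDC", "B-cell", "CD8 T-cell", "Cytotoxic cell", "DC", "Eosinophils",
    "iDC", "Macrophages", "Mast cell", "Neutrophils", "NK CD56bright cell",
    "NK CD56dim cell", "NK cell", "pDC", "T helper cell", "T-cell", "Tcm",
    "Tem", "TFH", "Tgd", "Th1 cell", "Th17 cell", "Th2 cell", "Treg",
)

RESPONSE_CATEGORIES = ("Adaptive", "Innate", "Inflammation", "Humoral")

# real marker symbols seeded into the panel so closed-form scores (CYT,
# Treg/FOXP3) and the Teff signature have their canonical genes
_SPECIAL_SEEDS = {
    "Treg": "FOXP3",
    "Cytotoxic cell": "GZMA",
    "NK cell": "PRF1",
    "CD8 T-cell": "CD8A",
    "Th1 cell": "TBX21",
    "T-cell": "CD3E",
    "B-cell": "CD19",
}

# effector-T-cell marker pool; the panel's Teff signature is its intersection
# with the endogenous gene space
_TEFF_POOL = ("CD8A", "GZMA", "GZMB", "PRF1", "IFNG", "EOMES", "CXCL9", "CXCL10", "TBX21")

_EXTRA_SYMBOLS = ("GZMB", "IFNG", "EOMES", "CXCL9", "CXCL10")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Cohort-generator settings; the defaults mirror the discovery design
    (127 NanoString-profiled patients, 24 recurrences, 770-gene panel with
    40 housekeeping genes and 6 positive / 8 negative spike-in controls).

    library_size_sd is the log2-scale SD of the per-sample library factor;
    dispersion is the negative-binomial dispersion (variance mu + disp*mu^2,
    0 = Poisson); effect_map maps signature name -> planted log2 fold change
    in recurrent vs non-recurrent samples; til_link_strength couples the
    per-slide foci mean to the latent T-cell level (0 = independent).
    """

    n_samples: int = 127
    recurrence_fraction: float = 24 / 127
    n_endogenous: int = 730
    n_housekeeping: int = 40
    n_pos_controls: int = 6
    n_neg_controls: int = 8
    library_size_sd: float = 0.15
    dispersion: float = 0.05
    effect_map: dict[str, float] = field(default_factory=dict)
    til_link_strength: float = 1.0
    tcell_latent_sd: float = 1.0
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    pos_control_scale: float = 200.0
    neg_control_mean: float = 4.0
    foci_base_rate: float = 0.5
    category_overlap_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_endogenous", "n_housekeeping", "n_pos_controls", "n_neg_controls"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be a positive integer")
        if not (0.0 < self.recurrence_fraction < 1.0):
            raise SimulationError("recurrence_fraction must be strictly between 0 and 1")
        if self.library_size_sd < 0 or self.dispersion < 0 or self.tcell_latent_sd < 0:
            raise SimulationError("library_size_sd, dispersion and tcell_latent_sd must be >= 0")
        if self.til_link_strength < 0:
            raise SimulationError("til_link_strength must be >= 0")

    def streams(self) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return [np.random.default_rng(c) for c in children]


@dataclass
class Panel:
    """Probe table (Name -> CodeClass) plus the signature registry."""

    probes: pd.DataFrame
    signatures: SignatureRegistry

    @property
    def endogenous(self) -> list[str]:
        return list(self.probes.index[self.probes["CodeClass"] == CLASS_ENDOGENOUS])

    @property
    def housekeeping(self) -> list[str]:
        return list(self.probes.index[self.probes["CodeClass"] == CLASS_HOUSEKEEPING])


@dataclass
class CohortTruth:
    """Planted latent values: everything the generator knows and the analysis
    must recover."""

    log2fc: pd.Series          # per-gene planted recurrent-vs-non log2FC
    latent_tcell: pd.Series    # per-sample latent T-cell level (log2 scale)
    library_factors: pd.Series
    labels: pd.Series          # 'recurrent' / 'non_recurrent'
    baselines: pd.Series       # per-gene baseline mean count (linear scale)


@dataclass
class SimulatedCohort:
    raw_counts: RawCountMatrix
    annotation: pd.DataFrame
    truth: CohortTruth


def build_panel(config: SimulationConfig) -> Panel:
    """Construct the probe list and signature memberships.

    Each of the 24 cell types gets a disjoint block of endogenous genes
    (Treg is the singleton FOXP3); the Teff signature is the intersection of
    a canonical effector marker pool with the gene space; the 4 response
    categories partition the endogenous genes with a configurable fraction
    assigned to a second category so that the clustering overlap-exclusion
    rule has work to do.
    """
    config.validate()
    n_cell_types = len(CELL_TYPES)
    if config.n_endogenous < n_cell_types:
        raise SimulationError(
            f"n_endogenous={config.n_endogenous} cannot host one seed gene per "
            f"{n_cell_types} cell-type signatures"
        )
    rng = config.streams()[0]

    filler = (f"IMM{i:04d}" for i in range(1, config.n_endogenous + 1))
    seed_genes = [_SPECIAL_SEEDS.get(ct) or next(filler) for ct in CELL_TYPES]
    genes = list(seed_genes)
    for sym in _EXTRA_SYMBOLS:
        if len(genes) < config.n_endogenous:
            genes.append(sym)
    while len(genes) < config.n_endogenous:
        genes.append(next(filler))

    members: dict[str, list[str]] = {
        ct: [g] for ct, g in zip(CELL_TYPES, seed_genes)
    }
    pool = genes[n_cell_types:]
    rng.shuffle(pool)
    budget = min(len(pool), int(0.6 * config.n_endogenous))
    cursor = 0
    for ct in CELL_TYPES:
        if ct == "Treg":
            continue  # exactly one gene: FOXP3
        want = int(rng.integers(4, 25))
        take = min(want, budget - cursor)
        if take <= 0:
            continue
        members[ct].extend(pool[cursor : cursor + take])
        cursor += take

    registry = SignatureRegistry(
        [GeneSignature(ct, frozenset(members[ct]), KIND_CELL_TYPE) for ct in CELL_TYPES]
    )

    # response categories: primary assignment for every endogenous gene plus
    # a second category for a random fraction (partial overlap)
    primary = rng.integers(0, 4, size=len(genes))
    second = rng.integers(0, 4, size=len(genes))
    overlap = rng.random(len(genes)) < config.category_overlap_fraction
    cat_members: dict[str, set[str]] = {c: set() for c in RESPONSE_CATEGORIES}
    for g, p, s, ov in zip(genes, primary, second, overlap):
        cat_members[RESPONSE_CATEGORIES[p]].add(g)
        if ov and s != p:
            cat_members[RESPONSE_CATEGORIES[s]].add(g)
    for cat in RESPONSE_CATEGORIES:
        if cat_members[cat]:
            registry.add(GeneSignature(cat, frozenset(cat_members[cat]), KIND_CATEGORY))

    teff = [g for g in _TEFF_POOL if g in set(genes)]
    registry.add(GeneSignature("Teff", frozenset(teff), KIND_TEFF))

    hk = [f"HK{i:03d}" for i in range(1, config.n_housekeeping + 1)]
    pos = [f"POS_{chr(65 + i)}" for i in range(config.n_pos_controls)]
    neg = [f"NEG_{chr(65 + i)}" for i in range(config.n_neg_controls)]
    probes = pd.DataFrame(
        {
            "CodeClass": (
                [CLASS_ENDOGENOUS] * len(genes)
                + [CLASS_HOUSEKEEPING] * len(hk)
                + [CLASS_POSITIVE] * len(pos)
                + [CLASS_NEGATIVE] * len(neg)
            )
        },
        index=pd.Index(genes + hk + pos + neg, name="Name"),
    )
    return Panel(probes, registry)


def positive_control_ladder(n: int) -> np.ndarray:
    """Spike-in concentration ladder: 4-fold steps from 128 down (128, 32, ...)."""
    return 128.0 * 4.0 ** (-np.arange(n))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture; dispersion 0 -> Poisson."""
    if dispersion == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_counts(panel: Panel, config: SimulationConfig) -> SimulatedCohort:
    """Draw the raw count matrix, recurrence labels and clinical covariates.

    Endogenous/housekeeping counts are negative binomial with mean
    ``library_factor * baseline_g * 2**(effect_g * recurrent + latent_t *
    in_tcell_sig)``; positive controls follow the concentration ladder scaled
    by the library factor (Poisson); negative controls are low-mean Poisson,
    independent of biology and library size.
    """
    config.validate()
    rng = config.streams()[1]
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(1, n + 1)]

    recurrent = rng.random(n) < config.recurrence_fraction
    labels = pd.Series(
        np.where(recurrent, "recurrent", "non_recurrent"), index=samples, name="recurrence"
    )

    bio_genes = panel.endogenous + panel.housekeeping
    g = len(bio_genes)
    baselines = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=g)
    lib = 2.0 ** rng.normal(0.0, config.library_size_sd, size=n)
    latent = rng.normal(0.0, config.tcell_latent_sd, size=n)

    effect = np.zeros(g)
    gene_pos = {gene: i for i, gene in enumerate(bio_genes)}
    for sig_name, lfc in config.effect_map.items():
        if sig_name not in panel.signatures:
            raise SimulationError(f"effect_map names unknown signature {sig_name!r}")
        for gene in panel.signatures[sig_name].genes:
            if gene in gene_pos:
                effect[gene_pos[gene]] += lfc

    in_tcell = np.zeros(g)
    if "T-cell" in panel.signatures:
        for gene in panel.signatures["T-cell"].genes:
            if gene in gene_pos:
                in_tcell[gene_pos[gene]] = 1.0

    log2_mu = (
        np.log2(baselines)[:, None]
        + effect[:, None] * recurrent[None, :].astype(float)
        + in_tcell[:, None] * latent[None, :]
    )
    mu = lib[None, :] * 2.0 ** log2_mu
    bio_counts = _nb_draw(rng, mu, config.dispersion)

    ladder = positive_control_ladder(config.n_pos_controls)
    pos_mu = config.pos_control_scale * ladder[:, None] * lib[None, :]
    pos_counts = rng.poisson(pos_mu)
    neg_counts = rng.poisson(
        np.full((config.n_neg_controls, n), config.neg_control_mean)
    )

    counts = pd.DataFrame(
        np.vstack([bio_counts, pos_counts, neg_counts]).astype(float),
        index=panel.probes.index,
        columns=samples,
    )
    raw = RawCountMatrix(counts, panel.probes["CodeClass"].copy())

    # clinical covariates drawn conditional on the recurrence label, with
    # probabilities matching the published cohort marginals
    necrosis = rng.random(n) < np.where(recurrent, 0.55, 0.25)
    grade_hi = rng.random(n) < np.where(recurrent, 0.82, 0.70)
    stage_hi = rng.random(n) < np.where(recurrent, 0.70, 0.55)
    annotation = pd.DataFrame(
        {
            "recurrence": labels,
            "grade": np.where(grade_hi, "3-4", "1-2"),
            "necrosis": np.where(necrosis, "yes", "no"),
            "stage": np.where(stage_hi, ">T1", "T1"),
        },
        index=pd.Index(samples, name="sample_id"),
    )

    truth = CohortTruth(
        log2fc=pd.Series(effect, index=bio_genes, name="log2fc"),
        latent_tcell=pd.Series(latent, index=samples, name="latent_tcell"),
        library_factors=pd.Series(lib, index=samples, name="library_factor"),
        labels=labels,
        baselines=pd.Series(baselines, index=bio_genes, name="baseline"),
    )
    return SimulatedCohort(raw, annotation, truth)


def simulate_foci(truth: CohortTruth, config: SimulationConfig) -> dict[str, list[int]]:
    """Per-sample per-slide TIL foci counts.

    Each sample gets 1-10 H&E slides (uniform); per-slide foci counts are
    Poisson with mean ``foci_base_rate * 2**(til_link_strength * latent)``,
    so til_link_strength=0 decouples foci from the latent T-cell level.
    """
    config.validate()
    rng = config.streams()[2]
    foci: dict[str, list[int]] = {}
    for sample, latent in truth.latent_tcell.items():
        n_slides = int(rng.integers(1, 11))
        mean = config.foci_base_rate * 2.0 ** (config.til_link_strength * latent)
        foci[sample] = [int(x) for x in rng.poisson(mean, size=n_slides)]
    return foci


def simulate_cohort(config: SimulationConfig) -> tuple[Panel, SimulatedCohort]:
    """Panel + counts + foci + derived TIL score in one call."""
    panel = build_panel(config)
    cohort = simulate_counts(panel, config)
    foci = simulate_foci(cohort.truth, config)
    cohort.annotation["foci"] = pd.Series(
        {s: ";".join(map(str, v)) for s, v in foci.items()}
    )
    cohort.annotation["til_score"] = pd.Series(
        {s: min(max(v), 4) for s, v in foci.items()}
    )
    return panel, cohort


def write_annotation_csv(annotation: pd.DataFrame, path: str) -> None:
    """CSV with columns sample_id, recurrence, grade, necrosis, stage, foci
    (semicolon-joined per-slide counts), til_score."""
    annotation.to_csv(path, index=True)
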