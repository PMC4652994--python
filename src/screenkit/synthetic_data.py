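"""Synthetic inputs for every stage of the screen/cohort pipeline.

The generators emulate the study conditions of an in vivo pooled shRNA
screen in patient-derived glioblastoma models and its companion cohort
analyses:

* a barcoded lentiviral library (~200 shRNAs, 24 genes, 5-7 hairpins each)
  transduced at MOI 1 and injected at a 100,000-cell bottleneck (~500 cells
  per hairpin), with Wright-Fisher drift plus selection over tumor growth
  and multinomial (or Dirichlet-multinomial) sequencing;
* single-hit Poisson limiting-dilution well outcomes;
* a subtype-structured expression cohort in which an NLK-like marker gene
  is anticorrelated with coupled WNT / mesenchymal metagene activities, with
  matched copy-number and survival tables;
* comparative-Ct qPCR fixtures.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, SimulationError
from .lda import LdaExperiment
from .screen_quant import BarcodeMap, ScreenCounts

SUBTYPES = ("Proneural", "Neural", "Classical", "Mesenchymal")
_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Screen library and simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenLibrary:
    """Barcoded shRNA library.

    One row per hairpin: shrna_id, gene, barcode (fixed length), knockdown
    efficacy in [0,1], and the per-doubling selection coefficient of the
    targeted gene (0 for neutral genes).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        for col in ("shrna_id", "gene", "barcode", "knockdown_efficacy", "gene_effect"):
            if col not in t.columns:
                raise InvalidParameterError(f"library missing column {col!r}")
        if t["shrna_id"].duplicated().any() or t["barcode"].duplicated().any():
            raise InvalidParameterError("shrna_ids and barcodes must be unique")
        if t["barcode"].str.len().nunique() != 1:
            raise InvalidParameterError("barcodes must have equal length")
        eff = t["knockdown_efficacy"]
        if ((eff < 0) | (eff > 1)).any():
            raise InvalidParameterError("knockdown_efficacy must lie in [0, 1]")
        if (t.groupby("gene").size() < 1).any():
            raise InvalidParameterError("every gene needs >=1 shRNA")

    def __len__(self):
        return len(self.table)

    @property
    def barcode_length(self) -> int:
        return len(self.table["barcode"].iloc[0])

    @property
    def fitness(self) -> np.ndarray:
        """Per-hairpin Wright-Fisher fitness w = 1 + efficacy * gene_effect."""
        t = self.table
        return 1.0 + t["knockdown_efficacy"].to_numpy() * t["gene_effect"].to_numpy()

    def barcode_map(self) -> BarcodeMap:
        return BarcodeMap(self.table[["barcode", "shrna_id", "gene"]].copy())

    @property
    def genes(self) -> list:
        return sorted(self.table["gene"].unique())


def _random_barcodes(n: int, length: int, rng: np.random.Generator) -> list:
    seen, out = set(), []
    while len(out) < n:
        bc = "".join(rng.choice(_BASES, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def make_library(
    n_genes: int = 24,
    shrnas_per_gene: tuple = (5, 7),
    barcode_length: int = 21,
    driver_effects: Mapping[str, float] | None = None,
    driver_efficacy: float | None = None,
    efficacy_beta: tuple = (5.0, 2.0),
    seed: int = 0,
) -> ScreenLibrary:
    """Build a synthetic barcoded library.

    ``driver_effects`` maps driver gene names (e.g. tumor suppressors whose
    knockdown confers a growth advantage) to per-doubling selection
    coefficients; the remaining genes up to ``n_genes`` are neutral.
    Knockdown efficacies are Beta(5, 2) draws unless ``driver_efficacy``
    pins the driver hairpins to a fixed value.
    """
    rng = np.random.default_rng(seed)
    driver_effects = dict(driver_effects or {})
    if len(driver_effects) > n_genes:
        raise InvalidParameterError("more drivers than genes")
    genes = list(driver_effects)
    genes += [f"GENE{i:03d}" for i in range(1, n_genes - len(driver_effects) + 1)]
    lo, hi = shrnas_per_gene
    rows = []
    for gene in genes:
        k = int(rng.integers(lo, hi + 1))
        effect = driver_effects.get(gene, 0.0)
        for j in range(1, k + 1):
            eff = float(rng.beta(*efficacy_beta))
            if gene in driver_effects and driver_efficacy is not None:
                eff = driver_efficacy
            rows.append((f"{gene}.sh{j}", gene, eff, effect))
    df = pd.DataFrame(rows, columns=["shrna_id", "gene", "knockdown_efficacy", "gene_effect"])
    df.insert(2, "barcode", _random_barcodes(len(df), barcode_length, rng))
    return ScreenLibrary(df)


@dataclass
class SimConfig:
    """Parameters of one simulated in vivo screen.

    ``n_genes``, ``shrnas_per_gene`` and ``moi`` describe library
    construction / infection and are consumed by :func:`make_library` and
    :func:`simulate_infection`; the population-dynamics fields drive
    :func:`simulate_screen`.  ``overdispersion`` is the Dirichlet
    concentration of the sequencing step (``inf`` = pure multinomial).
    """

    n_genes: int = 24
    shrnas_per_gene: tuple = (5, 7)
    moi: float = 1.0
    post_selection_cells: int = 1_000_000
    bottleneck_cells: int = 100_000
    doublings: int = 15
    carrying_capacity: int = 10_000_000
    reads_per_sample: int = 2_000_000
    overdispersion: float = np.inf
    n_lines: int = 3
    tumors_per_line: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_genes", "post_selection_cells", "bottleneck_cells",
            "carrying_capacity", "reads_per_sample", "n_lines", "tumors_per_line",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.doublings < 0:
            raise InvalidParameterError("doublings must be >= 0")
        if not self.moi > 0:
            raise InvalidParameterError("moi must be > 0")
        if not self.overdispersion > 0:
            raise InvalidParameterError("overdispersion must be > 0")


def simulate_infection(n_cells: int, moi: float, seed: int = 0) -> dict:
    """Poisson(moi) lentiviral integrations per cell.

    Cells with zero integrations are flagged as removed by antibiotic
    selection.  Returns the integration counts plus infected and
    single-integration summary fractions.
    """
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be >= 1")
    if not moi > 0:
        raise InvalidParameterError("moi must be > 0")
    rng = np.random.default_rng(seed)
    k = rng.poisson(moi, size=int(n_cells))
    infected = k > 0
    n_inf = int(infected.sum())
    return {
        "integrations": k,
        "removed_by_selection": ~infected,
        "infected_fraction": n_inf / n_cells,
        "single_integration_fraction": float((k == 1).sum() / n_inf) if n_inf else np.nan,
    }


def _draw_reads(p: np.ndarray, reads: int, overdispersion: float, rng) -> np.ndarray:
    """Multinomial or Dirichlet-multinomial sequencing draw from proportions p."""
    if np.isinf(overdispersion):
        return rng.multinomial(reads, p)
    pos = p > 0
    alpha = overdispersion * p[pos]
    q = rng.dirichlet(alpha)
    out = np.zeros_like(p)
    out[pos] = rng.multinomial(reads, q)
    return out


def simulate_screen(
    library: ScreenLibrary,
    config: SimConfig,
    expectation: bool = False,
) -> tuple:
    """Simulate the pooled in vivo screen; returns (control, [tumors]).

    Stages per tumor: (1) post-selection population with equal expected
    representation, sampled once and shared by all tumors and the control;
    (2) injection bottleneck, a multinomial draw of ``bottleneck_cells``;
    (3) per-doubling Wright-Fisher resampling with fitness
    w = 1 + efficacy * gene_effect and population size
    N_t = min(N0 * 2^t, carrying_capacity); (4) sequencing.  The control is
    sequenced directly from the stage-1 proportions (collected at injection
    time, no in vivo growth).

    With ``expectation=True`` all sampling is replaced by its expectation
    (drift disabled, real-valued counts): tumor proportions follow
    p_i w_i^D / sum_j p_j w_j^D exactly.
    """
    if len(library) == 0:
        raise InvalidParameterError("empty library")
    rng = np.random.default_rng(config.seed)
    S = len(library)
    ids = library.table["shrna_id"]
    w = library.fitness
    p_equal = np.full(S, 1.0 / S)

    def pack(arr, sample_id, role, line_id):
        return ScreenCounts(sample_id, role, line_id, pd.Series(arr, index=ids, name="count"))

    if expectation:
        stage1_p = p_equal
        control = pack(config.reads_per_sample * stage1_p, "control", "control", "control")
        tumors = []
        for li in range(1, config.n_lines + 1):
            for ti in range(1, config.tumors_per_line + 1):
                p = stage1_p.copy()
                for _ in range(config.doublings):
                    p = p * w
                    p /= p.sum()
                tumors.append(
                    pack(config.reads_per_sample * p, f"L{li}_T{ti}", "tumor", f"L{li}")
                )
        return control, tumors

    stage1 = rng.multinomial(config.post_selection_cells, p_equal)
    if stage1.sum() == 0:
        raise SimulationError("post-selection population went extinct")
    stage1_p = stage1 / stage1.sum()
    control = pack(
        _draw_reads(stage1_p, config.reads_per_sample, config.overdispersion, rng),
        "control", "control", "control",
    )
    tumors = []
    for li in range(1, config.n_lines + 1):
        for ti in range(1, config.tumors_per_line + 1):
            cells = rng.multinomial(config.bottleneck_cells, stage1_p)
            N = config.bottleneck_cells
            for _ in range(config.doublings):
                N = min(N * 2, config.carrying_capacity)
                fit = cells * w
                total = fit.sum()
                if total <= 0:
                    raise SimulationError(
                        f"tumor L{li}_T{ti}: population extinct during growth"
                    )
                cells = rng.multinomial(N, fit / total)
            if cells.sum() == 0:
                raise SimulationError(f"tumor L{li}_T{ti}: harvested population empty")
            p_final = cells / cells.sum()
            tumors.append(
                pack(
                    _draw_reads(p_final, config.reads_per_sample, config.overdispersion, rng),
                    f"L{li}_T{ti}", "tumor", f"L{li}",
                )
            )
    return control, tumors


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadLayout:
    """Read structure: fixed prefix, the barcode, fixed suffix.  Offset = len(prefix)."""

    prefix: str = ""
    suffix: str = ""

    @property
    def offset(self) -> int:
        return len(self.prefix)


def write_barcode_fastq(
    counts,
    library: ScreenLibrary,
    path,
    reads: int,
    layout: ReadLayout = ReadLayout(),
    error_rate: float = 0.0,
    seed: int = 0,
):
    """Emit a 4-line FASTQ of barcode reads sampled from a population.

    ``counts`` is a ScreenCounts or a per-shRNA Series of cell/read
    abundances; ``reads`` reads are drawn multinomially from its
    composition.  Each read embeds the hairpin barcode between the layout
    flanks with independent per-base substitution errors at ``error_rate``.
    Qualities are constant 'I' (Phred+33, Q40).
    """
    if reads <= 0:
        raise InvalidParameterError("reads must be > 0")
    if not 0 <= error_rate <= 0.1:
        raise InvalidParameterError("error_rate must lie in [0, 0.1]")
    c = counts.counts if isinstance(counts, ScreenCounts) else counts
    c = c.reindex(library.table["shrna_id"]).fillna(0.0).to_numpy(dtype=float)
    if c.sum() <= 0:
        raise InvalidParameterError("empty population: nothing to sequence")
    rng = np.random.default_rng(seed)
    per_shrna = rng.multinomial(reads, c / c.sum())
    barcodes = library.table["barcode"].to_numpy()
    L = library.barcode_length
    code = {c_: i for i, c_ in enumerate("ACGT")}
    enc = np.array([[code[b] for b in bc] for bc in barcodes], dtype=np.uint8)
    seq_mat = np.repeat(enc, per_shrna, axis=0)
    origin = np.repeat(library.table["shrna_id"].to_numpy(), per_shrna)
    if error_rate > 0:
        mask = rng.random(seq_mat.shape) < error_rate
        shift = rng.integers(1, 4, size=seq_mat.shape, dtype=np.uint8)
        seq_mat = np.where(mask, (seq_mat + shift) % 4, seq_mat)
    qual = "I" * (len(layout.prefix) + L + len(layout.suffix))
    lut = np.array(list("ACGT"))
    with open(path, "w") as fh:
        for i in range(seq_mat.shape[0]):
            seq = layout.prefix + "".join(lut[seq_mat[i]]) + layout.suffix
            fh.write(f"@read{i}|{origin[i]}\n{seq}\n+\n{qual}\n")
    return pd.Series(per_shrna, index=library.table["shrna_id"], name="sampled_reads")


# ---------------------------------------------------------------------------
# Limiting dilution wells
# ---------------------------------------------------------------------------

def generate_lda_wells(
    frequency: float,
    doses: Sequence[int] = (1, 5, 10, 20, 50),
    wells_per_dose: int = 500,
    seed: int = 0,
    condition: str = "synthetic",
) -> LdaExperiment:
    """Single-hit Poisson well outcomes: each well negative w.p. exp(-f * dose)."""
    if not 0 < frequency <= 1:
        raise InvalidParameterError("frequency must lie in (0, 1]")
    if any(d <= 0 for d in doses):
        raise InvalidParameterError("doses must be positive")
    if wells_per_dose <= 0:
        raise InvalidParameterError("wells_per_dose must be positive")
    rng = np.random.default_rng(seed)
    rows = [
        (d, wells_per_dose, int(rng.binomial(wells_per_dose, np.exp(-frequency * d))))
        for d in doses
    ]
    return LdaExperiment(condition, pd.DataFrame(rows, columns=["dose", "wells", "negative_wells"]))


# ---------------------------------------------------------------------------
# Subtype-structured expression cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Configuration of the synthetic GBM expression cohort.

    Latent per-sample activities: W ~ N(0,1) (WNT) and
    M = rho * W + sqrt(1 - rho^2) * eps + delta * 1[Mesenchymal] (mesenchymal).
    Signature genes express their activity plus N(0, gene_noise_sd); each
    subtype additionally carries a block of subtype marker genes shifted by
    ``subtype_marker_shift`` so nearest-centroid classification is
    learnable.  The NLK-like marker gene is marker_means[subtype] + N(0,1),
    which couples low marker expression to the mesenchymal subtype.

    Defaults were calibrated by simulation (>=200 seeds) so that the
    bottom-24 marker group is ~75% Mesenchymal, the top-24 group ~50%
    Classical, and WNT/mesenchymal activity scores correlate at r ~ 0.87 on
    the union of the extreme groups.
    """

    n_samples: int = 165
    subtype_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "Proneural": 0.27, "Neural": 0.17, "Classical": 0.29, "Mesenchymal": 0.27,
        }
    )
    marker_gene: str = "NLK"
    marker_means: Mapping[str, float] = field(
        default_factory=lambda: {
            "Mesenchymal": -1.45, "Proneural": -0.45, "Neural": 0.7, "Classical": 0.49,
        }
    )
    activity_coupling: float = 0.97  # rho between latent WNT and mesenchymal
    mesenchymal_shift: float = 1.0  # delta added to M for Mesenchymal samples
    gene_noise_sd: float = 0.3
    wnt_signature_size: int = 50
    mes_signature_size: int = 50
    subtype_marker_genes: int = 30
    subtype_marker_shift: float = 1.5
    n_noise_genes: int = 200
    deleted_genes: Mapping[str, float] = field(default_factory=dict)  # gene -> deleted fraction
    deleted_copy_number: float = 1.0
    survival_hazard_ratio: float = 2.0
    baseline_mean_days: float = 600.0
    censor_days: float = 1825.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError("subtype proportions must sum to 1")
        if not -1.0 <= self.activity_coupling <= 1.0:
            raise InvalidParameterError("activity_coupling must lie in [-1, 1]")
        if self.gene_noise_sd < 0:
            raise InvalidParameterError("gene_noise_sd must be >= 0")
        if self.survival_hazard_ratio <= 0:
            raise InvalidParameterError("survival_hazard_ratio must be > 0")


@dataclass
class SyntheticCohort:
    """Generated cohort: genes x samples matrices plus per-sample truth."""

    expression: pd.DataFrame
    copy_number: pd.DataFrame
    subtypes: pd.Series
    survival: pd.DataFrame  # sample_id, time_days, event
    gene_sets: dict  # name -> list of genes
    latent: pd.DataFrame  # wnt, mesenchymal activities per sample
    config: CohortConfig


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Draw one synthetic cohort under ``config`` (deterministic given seed)."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    samples = [f"S{i:03d}" for i in range(1, n + 1)]
    names = list(cfg.subtype_proportions)
    probs = np.array([cfg.subtype_proportions[s] for s in names])
    zero_requested = [s for s in SUBTYPES if cfg.subtype_proportions.get(s, 0) == 0]
    if zero_requested:
        import warnings

        warnings.warn(f"subtypes with zero probability will not appear: {zero_requested}")
    subtype = pd.Series(rng.choice(names, size=n, p=probs), index=samples, name="subtype")

    rho = cfg.activity_coupling
    W = rng.normal(size=n)
    M = rho * W + np.sqrt(1 - rho**2) * rng.normal(size=n)
    M = M + cfg.mesenchymal_shift * (subtype.to_numpy() == "Mesenchymal")
    marker = np.array([cfg.marker_means[s] for s in subtype]) + rng.normal(size=n)

    wnt_genes = [f"WNTSIG{i:03d}" for i in range(1, cfg.wnt_signature_size + 1)]
    mes_genes = [f"MESSIG{i:03d}" for i in range(1, cfg.mes_signature_size + 1)]
    sub_genes = {
        s: [f"{s.upper()[:4]}MK{i:02d}" for i in range(1, cfg.subtype_marker_genes + 1)]
        for s in SUBTYPES
    }
    noise_genes = [f"NOISE{i:03d}" for i in range(1, cfg.n_noise_genes + 1)]

    blocks = {}
    for g in wnt_genes:
        blocks[g] = W + rng.normal(scale=cfg.gene_noise_sd, size=n)
    for g in mes_genes:
        blocks[g] = M + rng.normal(scale=cfg.gene_noise_sd, size=n)
    for s in SUBTYPES:
        is_s = (subtype.to_numpy() == s).astype(float)
        for g in sub_genes[s]:
            blocks[g] = cfg.subtype_marker_shift * is_s + rng.normal(
                scale=cfg.gene_noise_sd, size=n
            )
    blocks[cfg.marker_gene] = marker
    for g in noise_genes:
        blocks[g] = rng.normal(size=n)
    expr = pd.DataFrame(blocks, index=samples).T
    expr.index.name = "gene"

    cn = rng.normal(2.0, 0.1, size=expr.shape)
    cnv = pd.DataFrame(cn, index=expr.index, columns=samples)
    for gene, frac in cfg.deleted_genes.items():
        if gene not in cnv.index:
            continue
        hit = rng.random(n) < frac
        cnv.loc[gene, hit] = rng.normal(cfg.deleted_copy_number, 0.15, size=int(hit.sum()))

    # survival: exponential, marker-low quartile carries the elevated hazard
    q25 = np.quantile(marker, 0.25)
    low = marker <= q25
    mean_days = np.where(low, cfg.baseline_mean_days / cfg.survival_hazard_ratio,
                         cfg.baseline_mean_days)
    t = rng.exponential(mean_days)
    event = (t <= cfg.censor_days).astype(int)
    t = np.minimum(t, cfg.censor_days)
    survival = pd.DataFrame(
        {"sample_id": samples, "time_days": t, "event": event}
    )

    gene_sets = {"WNT_ACTIVITY": wnt_genes, "MESENCHYMAL": mes_genes}
    gene_sets.update({f"{s.upper()}_MARKERS": sub_genes[s] for s in SUBTYPES})
    latent = pd.DataFrame({"wnt": W, "mesenchymal": M}, index=samples)
    return SyntheticCohort(expr, cnv, subtype, survival, gene_sets, latent, cfg)


def generate_tumor_normal_matrices(
    n_genes: int = 500,
    n_tumors: int = 50,
    n_normals: int = 20,
    deleted_genes: Mapping[str, dict] | None = None,
    expr_sd: float = 1.0,
    seed: int = 0,
) -> dict:
    """Paired CNV/expression matrices with tumor/normal labels.

    ``deleted_genes`` maps gene name -> {"deletion_fraction": float,
    "copy_number": float, "expr_shift": float}; those genes carry focal
    copy-number loss in the stated fraction of tumors and a mean expression
    shift (negative = underexpressed) in all tumors.  All other genes are
    diploid noise, identical between groups.
    """
    rng = np.random.default_rng(seed)
    deleted_genes = deleted_genes or {}
    extra = [g for g in deleted_genes if not g.startswith("GENE")]
    base = [f"GENE{i:04d}" for i in range(1, n_genes - len(extra) + 1)]
    genes = extra + base
    tumors = [f"T{i:03d}" for i in range(1, n_tumors + 1)]
    normals = [f"N{i:03d}" for i in range(1, n_normals + 1)]
    samples = tumors + normals
    expr = pd.DataFrame(
        rng.normal(scale=expr_sd, size=(len(genes), len(samples))),
        index=genes, columns=samples,
    )
    cnv = pd.DataFrame(
        rng.normal(2.0, 0.1, size=(len(genes), len(samples))),
        index=genes, columns=samples,
    )
    for gene, spec_ in deleted_genes.items():
        frac = spec_.get("deletion_fraction", 0.3)
        cn_level = spec_.get("copy_number", 1.0)
        shift = spec_.get("expr_shift", -2.0)
        hit = rng.random(n_tumors) < frac
        cnv.loc[gene, np.array(tumors)[hit]] = rng.normal(cn_level, 0.1, int(hit.sum()))
        expr.loc[gene, tumors] += shift
    labels = pd.Series(
        ["tumor"] * n_tumors + ["normal"] * n_normals, index=samples, name="label"
    )
    expr.index.name = cnv.index.name = "gene"
    return {"cnv": cnv, "expr": expr, "labels": labels}


# ---------------------------------------------------------------------------
# qPCR Ct fixtures
# ---------------------------------------------------------------------------

def generate_ct_table(
    true_fold_changes: Mapping[str, float],
    reference_gene: str = "ACTB",
    calibrator_sample: str = "control",
    test_sample: str = "treated",
    replicates: int = 2,
    ct_noise_sd: float = 0.0,
    baseline_ct: float = 25.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Comparative-Ct fixture: Ct = baseline - log2(quantity) + noise.

    The reference gene has constant quantity in both samples; each target
    gene has quantity 1 in the calibrator and ``true_fold_changes[gene]`` in
    the test sample.
    """
    if any(f <= 0 for f in true_fold_changes.values()):
        raise InvalidParameterError("fold changes must be > 0")
    if replicates < 1:
        raise InvalidParameterError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    quantities = {
        calibrator_sample: {reference_gene: 1.0, **{g: 1.0 for g in true_fold_changes}},
        test_sample: {reference_gene: 1.0, **dict(true_fold_changes)},
    }
    for sample, qty in quantities.items():
        for gene, q in qty.items():
            for rep in range(1, replicates + 1):
                ct = baseline_ct - np.log2(q) + rng.normal(scale=ct_noise_sd)
                rows.append((sample, gene, rep, float(ct)))
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])
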