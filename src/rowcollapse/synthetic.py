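"""Seeded generators emulating the data structures the analyses assume.

Three regimes are covered, each with the latent structure its analysis
exploits:

* probe->gene pairs — two datasets over the same probes, where each gene
  has a latent per-sample signal (a shared-loading factor model, so gene-
  gene correlations reproduce across datasets) and each probe reads that
  signal with its own signal fraction plus independent Gaussian noise.  One
  probe per gene is planted as the carrier: highest signal fraction and
  highest baseline, so max-mean selection should find it.
* co-expression modules — each module driven by a latent eigengene; member
  rows are loading x eigengene + noise, with the planted hub at the top
  loading.
* cell mixtures — pure profiles with planted fold-enriched markers per cell
  type; mixture samples are known convex combinations of the pure
  signatures with heteroscedastic multiplicative noise (per-gene noise
  multipliers are independent of expression level, so the most reliable
  marker of a type is generally not its most expressed one).

All outputs are bit-reproducible from the spec's seed, and generated
matrices/group maps satisfy the I/O layer's invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .deconvolve import scale_proportions


class SimulationSpecError(ValueError):
    pass


# --------------------------------------------------------------------------
# probe -> gene paired datasets


@dataclass(frozen=True)
class ProbeGeneSpec:
    """Paired probe-level datasets sharing gene-level structure.

    ``signal_fraction`` scales how strongly a non-carrier probe tracks its
    gene's unit-variance latent signal; the carrier probe always tracks at
    ``carrier_signal_fraction``.  ``n_factors`` latent factors with shared
    loadings induce reproducible gene-gene correlation across the two
    datasets.
    """

    seed: int = 0
    n_samples: int = 20
    n_genes: int = 50
    min_probes: int = 1
    max_probes: int = 4
    signal_fraction: float = 0.5
    carrier_signal_fraction: float = 0.9
    noise_sd: float = 1.0
    n_factors: int = 3
    baseline_mean: float = 8.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples <= 0:
            raise SimulationSpecError("counts must be positive")
        if not (0 <= self.signal_fraction <= 1 and 0 <= self.carrier_signal_fraction <= 1):
            raise SimulationSpecError("signal fractions must lie in [0, 1]")
        if self.min_probes < 1 or self.max_probes < self.min_probes:
            raise SimulationSpecError("invalid probes-per-gene range")
        if self.noise_sd < 0:
            raise SimulationSpecError("noise_sd must be non-negative")


@dataclass
class ProbeGenePair:
    dataset_a: pd.DataFrame
    dataset_b: pd.DataFrame
    groups: pd.Series
    planted_carriers: pd.Series  # gene -> probe id of the planted best probe
    spec: ProbeGeneSpec

    def manifest(self) -> dict:
        return {"spec": asdict(self.spec), "planted_carriers": self.planted_carriers.to_dict()}


def simulate_probe_gene_pair(spec: ProbeGeneSpec) -> ProbeGenePair:
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"g{i:04d}" for i in range(spec.n_genes)]
    probes_per_gene = rng.integers(spec.min_probes, spec.max_probes + 1, size=spec.n_genes)
    gene_baselines = spec.baseline_mean + rng.normal(0.0, 2.0, size=spec.n_genes)
    # shared factor loadings give genes a reproducible correlation structure
    loadings = rng.normal(0.0, 1.0, size=(spec.n_genes, spec.n_factors))
    loadings *= 0.8 / np.linalg.norm(loadings, axis=1, keepdims=True)
    resid_sd = np.sqrt(1.0 - np.sum(loadings**2, axis=1))

    probe_ids: list[str] = []
    probe_gene: list[str] = []
    carriers: dict[str, str] = {}
    fractions: list[float] = []
    offsets: list[float] = []
    for gi, gene in enumerate(gene_ids):
        n_probes = int(probes_per_gene[gi])
        carrier = int(rng.integers(n_probes))
        for pi in range(n_probes):
            pid = f"{gene}_p{pi}"
            probe_ids.append(pid)
            probe_gene.append(gene)
            if pi == carrier:
                carriers[gene] = pid
                fractions.append(spec.carrier_signal_fraction)
                offsets.append(gene_baselines[gi] + 1.0)  # planted highest baseline
            else:
                fractions.append(spec.signal_fraction)
                offsets.append(gene_baselines[gi] + float(rng.uniform(-1.0, 0.0)))

    def one_dataset() -> pd.DataFrame:
        factors = rng.normal(size=(spec.n_factors, spec.n_samples))
        gene_signal = loadings @ factors + resid_sd[:, None] * rng.normal(
            size=(spec.n_genes, spec.n_samples)
        )  # unit variance latent per gene
        gene_index = {g: i for i, g in enumerate(gene_ids)}
        rows = np.empty((len(probe_ids), spec.n_samples))
        for ri, (pid, gene) in enumerate(zip(probe_ids, probe_gene)):
            latent = gene_signal[gene_index[gene]]
            rows[ri] = offsets[ri] + fractions[ri] * latent + rng.normal(
                0.0, spec.noise_sd, size=spec.n_samples
            )
        return pd.DataFrame(
            rows, index=probe_ids, columns=[f"s{j:02d}" for j in range(spec.n_samples)]
        )

    a, b = one_dataset(), one_dataset()
    groups = pd.Series(probe_gene, index=probe_ids, name="gene")
    return ProbeGenePair(
        dataset_a=a,
        dataset_b=b,
        groups=groups,
        planted_carriers=pd.Series(carriers, name="carrier"),
        spec=spec,
    )


# --------------------------------------------------------------------------
# co-expression modules


@dataclass(frozen=True)
class ModuleSpec:
    """Modules of rows driven by latent eigengenes with known loadings."""

    seed: int = 0
    n_samples: int = 40
    module_sizes: tuple[int, ...] = (12,)
    hub_loading: float = 1.0
    member_loading_range: tuple[float, float] = (0.3, 0.55)
    noise_sd: float = 0.3
    baseline_mean: float = 8.0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.module_sizes) or not self.module_sizes:
            raise SimulationSpecError("module sizes must be positive")
        lo, hi = self.member_loading_range
        if not (0 <= lo <= hi):
            raise SimulationSpecError("invalid member loading range")
        if hi >= self.hub_loading:
            raise SimulationSpecError("hub loading must exceed member loadings")
        if self.noise_sd < 0:
            raise SimulationSpecError("noise_sd must be non-negative")


@dataclass
class ModuleData:
    matrix: pd.DataFrame
    groups: pd.Series  # row -> module label
    loadings: pd.Series  # row -> true loading on its module eigengene
    true_hubs: pd.Series  # module -> row id with maximum loading
    eigengenes: pd.DataFrame  # module x sample latent signals
    spec: ModuleSpec

    def manifest(self) -> dict:
        return {"spec": asdict(self.spec), "true_hubs": self.true_hubs.to_dict()}


def simulate_modules(spec: ModuleSpec) -> ModuleData:
    rng = np.random.default_rng(spec.seed)
    samples = [f"s{j:02d}" for j in range(spec.n_samples)]
    rows, row_ids, groups, loadings, hubs = [], [], {}, {}, {}
    eigengenes = {}
    for mi, size in enumerate(spec.module_sizes):
        module = f"M{mi}"
        eigengene = rng.normal(size=spec.n_samples)
        eigengenes[module] = eigengene
        lo, hi = spec.member_loading_range
        load = rng.uniform(lo, hi, size=size)
        hub_pos = int(rng.integers(size))
        load[hub_pos] = spec.hub_loading
        for ri in range(size):
            rid = f"{module}_r{ri}"
            row_ids.append(rid)
            groups[rid] = module
            loadings[rid] = float(load[ri])
            baseline = spec.baseline_mean + rng.normal(0.0, 1.0)
            rows.append(
                baseline + load[ri] * eigengene + rng.normal(0.0, spec.noise_sd, spec.n_samples)
            )
        hubs[module] = f"{module}_r{hub_pos}"
    matrix = pd.DataFrame(np.vstack(rows), index=row_ids, columns=samples)
    return ModuleData(
        matrix=matrix,
        groups=pd.Series(groups, name="module"),
        loadings=pd.Series(loadings, name="loading"),
        true_hubs=pd.Series(hubs, name="hub"),
        eigengenes=pd.DataFrame(eigengenes, index=samples).T,
        spec=spec,
    )


# --------------------------------------------------------------------------
# cell mixtures


def default_mixture_design(n_types: int, replicates: int = 3) -> np.ndarray:
    """Pre-specified mixing proportions: four distinct compositions run in
    triplicate for the four-type default, otherwise an evenly rotated set."""
    if n_types == 4:
        designs = np.array(
            [
                [0.25, 0.25, 0.25, 0.25],
                [0.05, 0.05, 0.45, 0.45],
                [0.45, 0.45, 0.05, 0.05],
                [0.10, 0.20, 0.30, 0.40],
            ]
        )
    else:
        base = np.linspace(1.0, n_types, n_types)
        designs = np.array([np.roll(base, k) for k in range(n_types)])
        designs = designs / designs.sum(axis=1, keepdims=True)
    return np.repeat(designs, replicates, axis=0).T  # types x samples


@dataclass(frozen=True)
class MixtureSpec:
    """Known convex combinations of pure cell-type profiles.

    ``marker_fold`` is the planted enrichment of each marker gene in its own
    type's pure profile; ``noise_cv`` the coefficient of variation of the
    multiplicative measurement noise, modulated per gene by a multiplier
    drawn from ``noise_multiplier_range`` (so reliability is independent of
    expression level).  ``proportions`` (types x samples) defaults to four
    pre-specified compositions in triplicate.
    """

    seed: int = 0
    n_cell_types: int = 4
    markers_per_type: int = 50
    n_background_genes: int = 100
    marker_fold: float = 8.0
    noise_cv: float = 0.0
    noise_multiplier_range: tuple[float, float] = (0.5, 2.0)
    pure_replicates: int = 3
    proportions: tuple[tuple[float, ...], ...] | None = None
    clamp_non_negative: bool = True

    def __post_init__(self) -> None:
        if self.n_cell_types < 2:
            raise SimulationSpecError("need at least 2 cell types")
        if self.markers_per_type < 1 or self.pure_replicates < 1:
            raise SimulationSpecError("counts must be positive")
        if self.marker_fold < 1:
            raise SimulationSpecError("marker_fold must be >= 1")
        if self.noise_cv < 0:
            raise SimulationSpecError("noise_cv must be non-negative")
        if self.proportions is not None:
            p = np.asarray(self.proportions, dtype=float)
            if p.ndim != 2 or p.shape[0] != self.n_cell_types:
                raise SimulationSpecError("proportions must be (n_cell_types x samples)")
            if (p < 0).any():
                raise SimulationSpecError("proportions must be non-negative")
            if (p.sum(axis=0) == 0).any():
                raise SimulationSpecError("a sample has zero total proportion")

    def proportion_matrix(self) -> np.ndarray:
        if self.proportions is not None:
            return np.asarray(self.proportions, dtype=float)
        return default_mixture_design(self.n_cell_types)


@dataclass
class MixtureData:
    pure: pd.DataFrame  # genes x pure replicate columns
    type_of_column: pd.Series  # pure column -> cell type
    mixtures: pd.DataFrame  # genes x mixture samples
    truth: pd.DataFrame  # types x samples, scaled to sum 1 per type
    planted_markers: dict[str, list[str]]
    spec: MixtureSpec

    def manifest(self) -> dict:
        return {"spec": asdict(self.spec), "planted_markers": self.planted_markers}


def simulate_mixture(spec: MixtureSpec) -> MixtureData:
    rng = np.random.default_rng(spec.seed)
    types = [f"T{t}" for t in range(spec.n_cell_types)]
    n_marker = spec.n_cell_types * spec.markers_per_type
    n_genes = n_marker + spec.n_background_genes
    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]

    base = rng.uniform(20.0, 100.0, size=n_genes)
    signature = np.tile(base[:, None], (1, spec.n_cell_types))
    planted: dict[str, list[str]] = {t: [] for t in types}
    for ti, t in enumerate(types):
        start = ti * spec.markers_per_type
        idx = np.arange(start, start + spec.markers_per_type)
        signature[idx, ti] = base[idx] * spec.marker_fold
        planted[t] = [gene_ids[i] for i in idx]

    noise_mult = rng.uniform(*spec.noise_multiplier_range, size=n_genes)

    def noisy(expected: np.ndarray) -> np.ndarray:
        if spec.noise_cv == 0:
            return expected.copy()
        eps = rng.normal(0.0, 1.0, size=expected.shape)
        values = expected * (1.0 + spec.noise_cv * noise_mult[:, None] * eps)
        return np.clip(values, 0.0, None) if spec.clamp_non_negative else values

    pure_cols, col_types = [], {}
    pure_values = []
    for ti, t in enumerate(types):
        expected = np.tile(signature[:, ti][:, None], (1, spec.pure_replicates))
        pure_values.append(noisy(expected))
        for r in range(spec.pure_replicates):
            col = f"{t}_rep{r}"
            pure_cols.append(col)
            col_types[col] = t
    pure = pd.DataFrame(np.hstack(pure_values), index=gene_ids, columns=pure_cols)

    proportions = spec.proportion_matrix()
    n_samples = proportions.shape[1]
    sample_ids = [f"mix{j:02d}" for j in range(n_samples)]
    mixtures = pd.DataFrame(
        noisy(signature @ proportions), index=gene_ids, columns=sample_ids
    )
    truth = scale_proportions(
        pd.DataFrame(proportions, index=types, columns=sample_ids)
    )
    return MixtureData(
        pure=pure,
        type_of_column=pd.Series(col_types, name="cell_type"),
        mixtures=mixtures,
        truth=truth,
        planted_markers=planted,
        spec=spec,
    )
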