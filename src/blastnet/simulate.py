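"""Synthetic cohorts with known ground truth for every pipeline input.

The generator emulates the statistical structure the downstream analyses
assume, not the raw instruments: a scored protein interactome (scale-free by
default, since interactome degree distributions are heavy-tailed), log2
expression matrices for a two-group cohort with differentially expressed
first-order neighbourhoods planted around chosen seed proteins, a labelled
reference cohort carrying a signed Ph-like expression signature,
mixture-of-lognormal flow-cytometry event tables with known modality and
score truth, and an end-of-induction MRD outcome table whose log level
depends on planted per-marker fold effects.

Genes and proteins share one symbol namespace (G0001, G0002, ...), so
expression p-values map directly onto interactome nodes.  Identical
configurations (including the seed) reproduce outputs bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .flow import PANEL, ReferenceInterval, SCORE_LEVELS, _default_class

__all__ = [
    "BELOW_LOD",
    "DEFAULT_BOUNDARIES",
    "PlantedNetwork",
    "FlowMarkerModel",
    "MrdModel",
    "SimulationConfig",
    "GroundTruth",
    "default_reference_intervals",
    "generate_ppi_graph",
    "generate_expression",
    "generate_phlike_reference",
    "generate_flow_cohort",
    "generate_control_events",
    "generate_outcome_cohort",
]

#: sentinel emitted for MRD values below the assay's limit of detection;
#: censoring to a number is a deliberate downstream step, never implicit
BELOW_LOD = "<LOD"

#: default four-level scoring boundaries on log10 fluorescence, shared by
#: the flow generator and its matching reference intervals
DEFAULT_BOUNDARIES: tuple[float, float, float] = (1.0, 2.0, 3.0)


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedNetwork:
    """A first-order neighbourhood carrying a log2 expression shift in group A."""

    seed: str
    effect_log2: float
    fraction_affected: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_affected <= 1.0:
            raise InvalidConfigError("fraction_affected must lie in (0, 1]")


@dataclass(frozen=True)
class FlowMarkerModel:
    """Gaussian mixture on log10 fluorescence for one marker."""

    means: tuple[float, ...] = (0.5,)
    sds: tuple[float, ...] = (0.15,)
    weights: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if not (len(self.means) == len(self.sds) == len(self.weights)):
            raise InvalidConfigError("means, sds and weights must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise InvalidConfigError(
                f"mixture weights must sum to 1, got {sum(self.weights)}"
            )
        if any(w <= 0 for w in self.weights) or any(s <= 0 for s in self.sds):
            raise InvalidConfigError("weights and sds must be positive")


@dataclass(frozen=True)
class MrdModel:
    """Log-linear model generating end-of-induction MRD levels.

    log10 MRD = intercept + sum of log10 fold effects for the patient's
    marker levels + log10(age fold) * age/10 + Gaussian noise.  Fold
    effects are keyed (marker, level) and expressed relative to the
    marker's reference level, mirroring how the fitted model reports them.
    """

    intercept_log10: float = -3.5
    fold_effects: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("CD34", "++"): 6.47, ("CD34", "+++"): 6.47}
    )
    age_fold_per_10y: float = 1.0
    noise_sd_log10: float = 1.0
    lod: float = 1e-5


def _default_flow_markers() -> dict[str, FlowMarkerModel]:
    """A panel mixing the three modalities at well-separated intensities."""
    out: dict[str, FlowMarkerModel] = {}
    for i, marker in enumerate(PANEL):
        kind = i % 3
        if kind == 0:  # unimodal positive-normal
            out[marker] = FlowMarkerModel(means=(2.5,), sds=(0.15,), weights=(1.0,))
        elif kind == 1:  # bimodal negative / positive-normal
            out[marker] = FlowMarkerModel(
                means=(0.5, 2.5), sds=(0.15, 0.15), weights=(0.4, 0.6)
            )
        else:  # broad single peak spanning > 1.5 score units
            out[marker] = FlowMarkerModel(means=(2.5,), sds=(0.55,), weights=(1.0,))
    return out


def _default_score_prevalences() -> dict[str, dict[str, float]]:
    return {m: {"-": 0.25, "+": 0.15, "++": 0.45, "+++": 0.15} for m in PANEL}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic world, with cohort-realistic defaults.

    Defaults echo the emulated study where it states a number: 100 000
    events per marker, a 160-sample expression cohort with 10 Ph-like
    cases, 20 vs 20 two-group comparisons at log2 noise SD 0.5, an MRD
    fold effect of 6.47 for CD34 normal-positive, and an assay limit of
    detection of 10^-5.
    """

    seed: int = 0
    # interactome
    n_proteins: int = 300
    edge_model: str = "scale_free"  # or "erdos_renyi"
    edge_density: float = 2.0  # attachment edges m (scale-free) or p (ER)
    confidence_distribution: tuple = ("uniform", 0.0, 1.0)
    # expression cohort
    n_genes: int = 2000
    n_samples_a: int = 20
    n_samples_b: int = 20
    planted_networks: list[PlantedNetwork] = field(default_factory=list)
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    n_duplicate_probe_genes: int = 1
    # Ph-like signature and cohorts
    phlike_signature_size: int = 170
    phlike_effect: float = 1.5
    n_phlike_samples: int = 160
    n_phlike: int = 10
    # flow cytometry
    flow_markers: dict[str, FlowMarkerModel] = field(default_factory=_default_flow_markers)
    n_events: int = 100_000
    n_flow_patients: int = 8
    # outcome cohort
    n_patients: int = 200
    score_prevalences: dict[str, dict[str, float]] = field(
        default_factory=_default_score_prevalences
    )
    mrd_model: MrdModel = field(default_factory=MrdModel)

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise InvalidConfigError("n_proteins must be >= 2")
        if self.n_genes < 1 or self.n_samples_a < 2 or self.n_samples_b < 2:
            raise InvalidConfigError("need n_genes >= 1 and >= 2 samples per group")
        if self.n_phlike > self.n_phlike_samples:
            raise InvalidConfigError("n_phlike cannot exceed n_phlike_samples")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one operation; streams never collide."""
        return np.random.default_rng([self.seed, stream])


# per-operation RNG stream ids
_STREAM_GRAPH = 1
_STREAM_EXPRESSION = 2
_STREAM_PHLIKE = 3
_STREAM_FLOW = 4
_STREAM_OUTCOME = 5
_STREAM_CONTROLS = 6


@dataclass
class GroundTruth:
    """Planted truth for one generated artefact; one record per entity."""

    de_gene_flags: pd.Series | None = None
    planted_network_members: dict[str, list[str]] | None = None
    probe_map: pd.DataFrame | None = None
    phlike_labels: pd.Series | None = None
    flow_truth: pd.DataFrame | None = None
    mrd_fold_effects: dict[tuple[str, str], float] | None = None


def _gene_symbols(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def generate_ppi_graph(config: SimulationConfig) -> nx.Graph:
    """Scored interactome over the shared gene-symbol namespace.

    Scale-free (Barabasi--Albert preferential attachment) by default;
    Erdos--Renyi with edge probability ``edge_density`` as the null model.
    Edge confidences are drawn i.i.d. from ``confidence_distribution``.
    """
    if config.n_proteins < 2:
        raise InvalidConfigError("n_proteins must be >= 2")
    rng = config.rng(_STREAM_GRAPH)
    n = config.n_proteins
    if config.edge_model == "scale_free":
        m = max(1, int(round(config.edge_density)))
        graph = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    elif config.edge_model == "erdos_renyi":
        graph = nx.gnp_random_graph(n, config.edge_density, seed=int(rng.integers(2**31)))
    else:
        raise InvalidConfigError(f"unknown edge model {config.edge_model!r}")
    symbols = _gene_symbols(config.n_genes if config.n_genes >= n else n)
    graph = nx.relabel_nodes(graph, {i: symbols[i] for i in range(n)})
    kind, *params = config.confidence_distribution
    n_edges = graph.number_of_edges()
    if kind == "uniform":
        lo, hi = params
        conf = rng.uniform(lo, hi, n_edges)
    elif kind == "beta":
        a, b = params
        conf = rng.beta(a, b, n_edges)
    elif kind == "point":
        conf = np.full(n_edges, float(params[0]))
    else:
        raise InvalidConfigError(f"unknown confidence distribution {kind!r}")
    for (u, v), c in zip(sorted(graph.edges()), conf):
        graph.edges[u, v]["confidence"] = float(np.clip(c, 0.0, 1.0))
    return graph


def generate_expression(
    config: SimulationConfig, graph: nx.Graph
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Two-group log2 expression with planted differential neighbourhoods.

    Returns (matrix genes x samples, labels, truth).  Members of each
    planted network are shifted by its log2 effect in group A only.
    """
    rng = config.rng(_STREAM_EXPRESSION)
    genes = _gene_symbols(config.n_genes)
    n_a, n_b = config.n_samples_a, config.n_samples_b
    samples = [f"S{i + 1:03d}" for i in range(n_a + n_b)]
    labels = pd.Series(["A"] * n_a + ["B"] * n_b, index=samples, name="group")

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    x = baseline[:, None] + rng.normal(0.0, config.noise_sd, (config.n_genes, n_a + n_b))
    matrix = pd.DataFrame(x, index=genes, columns=samples)

    de_flags = pd.Series(False, index=genes, name="differential")
    members_by_seed: dict[str, list[str]] = {}
    for planted in config.planted_networks:
        if planted.seed not in graph:
            raise InvalidConfigError(
                f"planted seed {planted.seed!r} is absent from the interactome"
            )
        members = sorted({planted.seed, *graph.neighbors(planted.seed)})
        members = [m for m in members if m in matrix.index]
        k = max(1, math.ceil(planted.fraction_affected * len(members)))
        affected = (
            members
            if k >= len(members)
            else sorted(rng.choice(members, size=k, replace=False))
        )
        matrix.loc[affected, labels == "A"] += planted.effect_log2
        de_flags.loc[affected] = planted.effect_log2 != 0
        members_by_seed[planted.seed] = affected

    probe_rows = [(f"P_{g}_1", g) for g in genes]
    for g in genes[: config.n_duplicate_probe_genes]:
        probe_rows.append((f"P_{g}_2", g))
    truth = GroundTruth(
        de_gene_flags=de_flags,
        planted_network_members=members_by_seed,
        probe_map=pd.DataFrame(probe_rows, columns=["probe", "gene"]),
    )
    return matrix, labels, truth


def make_phlike_signature(config: SimulationConfig) -> pd.DataFrame:
    """Signed probe-level signature table (probe, gene, factor).

    A couple of genes carry two probes with distinct factors, exercising
    the mean-factor resolution rule downstream.
    """
    rng = config.rng(_STREAM_PHLIKE)
    genes = _gene_symbols(config.n_genes)
    size = min(config.phlike_signature_size, config.n_genes)
    chosen = sorted(rng.choice(genes, size=size, replace=False))
    signs = rng.choice([-1.0, 1.0], size=size)
    mags = rng.uniform(0.2, 1.0, size=size)
    rows = [
        (f"P_{g}_1", g, float(s * m)) for g, s, m in zip(chosen, signs, mags)
    ]
    for g, s in list(zip(chosen, signs))[:2]:  # two genes with a second probe
        rows.append((f"P_{g}_2", g, float(s * rng.uniform(0.2, 1.0))))
    return pd.DataFrame(rows, columns=["probe", "gene", "factor"])


def generate_phlike_reference(
    config: SimulationConfig,
    signature: pd.DataFrame | None = None,
    n_samples: int | None = None,
    n_positive: int | None = None,
    stream: int = _STREAM_PHLIKE,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Labelled cohort in which positive samples carry the signature shift.

    Positive samples are shifted by ``phlike_effect * sign(factor)`` log2
    units on each signature gene, so the planted cases score high under the
    signed signature.  Used both for the reference dataset (to derive the
    top-25 filter) and, at cohort size, for consensus-recovery studies.
    """
    rng = config.rng(stream)
    signature = make_phlike_signature(config) if signature is None else signature
    n_samples = config.n_phlike_samples if n_samples is None else n_samples
    n_positive = config.n_phlike if n_positive is None else n_positive
    if n_positive > n_samples:
        raise InvalidConfigError("n_positive cannot exceed n_samples")

    genes = _gene_symbols(config.n_genes)
    samples = [f"R{i + 1:03d}" for i in range(n_samples)]
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    x = baseline[:, None] + rng.normal(0.0, config.noise_sd, (config.n_genes, n_samples))
    matrix = pd.DataFrame(x, index=genes, columns=samples)

    positive = sorted(rng.choice(samples, size=n_positive, replace=False)) if n_positive else []
    labels = pd.Series(False, index=samples, name="phlike")
    labels.loc[positive] = True
    per_gene = signature.groupby("gene")["factor"].mean()
    shift = config.phlike_effect * np.sign(per_gene)
    matrix.loc[per_gene.index, positive] += shift.to_numpy()[:, None]
    return matrix, labels, GroundTruth(phlike_labels=labels)


def default_reference_intervals(
    config: SimulationConfig | None = None,
) -> dict[str, ReferenceInterval]:
    """Reference intervals matching the generator's scoring boundaries."""
    markers = (config.flow_markers if config else _default_flow_markers()).keys()
    return {
        m: ReferenceInterval(
            marker=m, marker_class=_default_class(m), boundaries=DEFAULT_BOUNDARIES
        )
        for m in markers
    }


def _true_marker_record(
    patient: str, marker: str, model: FlowMarkerModel, ref: ReferenceInterval
) -> dict:
    """Intended modality / fractions / scores for one marker instance."""
    weights = np.asarray(model.weights)
    reported = weights > 0.01  # components at or below 1% are merged away
    comp_scores = [ref.classify(mu) for mu in model.means]
    n_reported = int(reported.sum())
    if n_reported >= 2:
        modality = "bimodal"
    else:
        # single reported component: broad iff the 10%-of-peak extent of its
        # Gaussian (full width at 10% max = 2 * sqrt(2 ln 10) * sd) spans
        # the 1.5-unit rule for this marker class
        sd = model.sds[int(np.argmax(weights))]
        extent = 2.0 * math.sqrt(2.0 * math.log(10.0)) * sd
        unit = 1.0 if ref.marker_class == "cross-lineage" else ref.score_unit
        modality = "broad" if extent >= 1.5 * unit else "unimodal"
    dominant = int(np.argmax(weights))
    return {
        "patient": patient,
        "marker": marker,
        "modality": modality,
        "weights": "/".join(f"{w:.4f}" for w in weights),
        "component_scores": "/".join(comp_scores),
        "overall_score": comp_scores[dominant],
    }


def generate_flow_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Per-patient event tables (one column per marker) plus score truth."""
    rng = config.rng(_STREAM_FLOW)
    refs = default_reference_intervals(config)
    tables: dict[str, pd.DataFrame] = {}
    records = []
    for i in range(config.n_flow_patients):
        patient = f"PT{i + 1:03d}"
        cols = {}
        for marker, model in config.flow_markers.items():
            comp = rng.choice(len(model.weights), size=config.n_events, p=model.weights)
            means = np.asarray(model.means)[comp]
            sds = np.asarray(model.sds)[comp]
            cols[marker] = rng.normal(means, sds)
            records.append(_true_marker_record(patient, marker, model, refs[marker]))
        tables[patient] = pd.DataFrame(cols)
    truth = GroundTruth(flow_truth=pd.DataFrame(records))
    return tables, truth


def generate_control_events(
    config: SimulationConfig,
    n_events_per_population: int = 20_000,
    neg_mean: float = 0.5,
    neg_sd: float = 0.2,
    pos_mean: float = 2.4,
    pos_sd: float = 0.5,
) -> tuple[dict[str, pd.DataFrame], dict[str, tuple[float, float, float]]]:
    """Normal-marrow control events for reference-interval derivation.

    Returns (control tables, true boundaries), where the true boundaries
    are the analytic quantiles of the generating Gaussians under the
    default quantile rule (99.5th percentile of the negative population,
    quartiles of the positive population).
    """
    rng = config.rng(_STREAM_CONTROLS)
    b1 = neg_mean + stats.norm.ppf(0.995) * neg_sd
    b2 = pos_mean + stats.norm.ppf(0.25) * pos_sd
    b3 = pos_mean + stats.norm.ppf(0.75) * pos_sd
    tables = {}
    truth = {}
    for marker in config.flow_markers:
        neg = rng.normal(neg_mean, neg_sd, n_events_per_population)
        pos = rng.normal(pos_mean, pos_sd, n_events_per_population)
        tables[marker] = pd.DataFrame(
            {
                "value": np.concatenate([neg, pos]),
                "population": ["negative"] * neg.size + ["positive"] * pos.size,
            }
        )
        truth[marker] = (b1, b2, b3)
    return tables, truth


def sample_marker_scores(
    config: SimulationConfig, n_patients: int | None = None
) -> pd.DataFrame:
    """Categorical four-level marker scores drawn from configured prevalences."""
    rng = config.rng(_STREAM_OUTCOME)
    n = config.n_patients if n_patients is None else n_patients
    patients = [f"PT{i + 1:03d}" for i in range(n)]
    cols = {}
    for marker, prev in config.score_prevalences.items():
        levels = list(prev)
        probs = np.array([prev[level] for level in levels], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise InvalidConfigError(f"{marker}: score prevalences must sum to 1")
        cols[marker] = rng.choice(levels, size=n, p=probs)
    return pd.DataFrame(cols, index=pd.Index(patients, name="patient"))


def generate_outcome_cohort(
    config: SimulationConfig,
    marker_scores: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Patient table with end-of-induction MRD, covariates and marker scores.

    MRD is lognormal around the configured fold-effect model; values below
    the limit of detection are emitted as the ``BELOW_LOD`` sentinel, never
    as a number, so censoring stays an explicit pipeline step.
    """
    if marker_scores is None:
        marker_scores = sample_marker_scores(config)
    rng = config.rng(_STREAM_OUTCOME + 100)
    model = config.mrd_model
    n = len(marker_scores)
    age = np.clip(rng.gamma(2.0, 3.5, n), 1.0, 45.0)
    wbc = np.round(rng.lognormal(math.log(9.0), 1.0, n), 1)

    log_mrd = np.full(n, model.intercept_log10)
    for (marker, level), fold in model.fold_effects.items():
        if marker not in marker_scores.columns:
            raise InvalidConfigError(f"fold effect refers to unknown marker {marker!r}")
        log_mrd += math.log10(fold) * (marker_scores[marker] == level).to_numpy()
    if model.age_fold_per_10y != 1.0:
        log_mrd += math.log10(model.age_fold_per_10y) * age / 10.0
    log_mrd += rng.normal(0.0, model.noise_sd_log10, n)
    mrd = np.minimum(10.0**log_mrd, 1.0)

    table = marker_scores.copy()
    table.insert(0, "mrd", [v if v >= model.lod else BELOW_LOD for v in mrd])
    table["age"] = np.round(age, 1)
    table["wbc"] = wbc
    truth = GroundTruth(mrd_fold_effects=dict(model.fold_effects))
    return table.reset_index(), truth
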