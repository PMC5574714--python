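"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates one of the study's input kinds:

* plate-reader growth curves — flat lag, exponential growth at a set doubling
  time, hard saturation cap, additive Gaussian read noise, plus matching
  medium-only blank wells;
* β-galactosidase induction assays — a transformed signal that is zero until
  the step time and rises linearly afterwards, re-encoded as raw A420/A540
  pairs that invert exactly through the background/time-zero-corrected
  sqrt(A420 − 1.75·A540) transform;
* homolog families — sequences diverged from a common random ancestor under
  a Poisson substitution process, with planted viability-discriminating
  columns held invariant in viable rows and mutated in ≥1 nonviable row;
* toy interactomes — preferential-attachment graphs with essential-node
  labels and an optional designated hub.

All randomness flows from the explicit ``seed`` carried by each parameter
object; no global random state is touched, and identical parameters give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .growth import PlateReaderSeries
from .network import Interactome
from .seqevo import LabeledAlignment, ProteinSequence
from .steptime import SCATTER_COEFF, InductionSeries

__all__ = [
    "SimulationError",
    "GrowthSimParams",
    "InductionSimParams",
    "FamilySimParams",
    "NetworkSimParams",
    "simulate_growth_curve",
    "simulate_induction_assay",
    "simulate_homolog_family",
    "simulate_interactome",
    "TABLE_STRAIN_PARAMS",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class SimulationError(ValueError):
    """Raised when generator parameters violate their invariants."""


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

@dataclass
class GrowthSimParams:
    """Ground truth for one strain's Bioscreen-style growth curves.

    ``initial_od``/``max_od`` are blank-corrected OD600 values; ``blank_od``
    is the medium-only background added to every emitted reading.  Times are
    minutes.  Noise is additive Gaussian on the raw OD, truncated so readings
    stay positive.
    """

    doubling_time: float
    lag_time: float
    max_od: float
    initial_od: float = 0.2
    blank_od: float = 0.09
    noise_sd: float = 0.0
    sample_interval: float = 5.0
    duration: float = 1440.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.doubling_time <= 0:
            raise SimulationError("doubling_time must be > 0")
        if not (0 <= self.lag_time < self.duration):
            raise SimulationError("lag_time must satisfy 0 <= lag < duration")
        if not (self.max_od > self.initial_od > 0):
            raise SimulationError("need max_od > initial_od > 0")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if self.sample_interval <= 0 or self.duration <= 0 or self.replicates < 1:
            raise SimulationError("sample_interval, duration and replicates must be positive")


def _true_corrected_od(t: np.ndarray, p: GrowthSimParams) -> np.ndarray:
    grown = p.initial_od * np.exp2((t - p.lag_time) / p.doubling_time)
    return np.where(t < p.lag_time, p.initial_od, np.minimum(p.max_od, grown))


def simulate_growth_curve(
    params: GrowthSimParams,
    strain_id: str = "strain",
) -> list[tuple[PlateReaderSeries, PlateReaderSeries]]:
    """Simulate (sample, blank) well pairs for one strain.

    The noiseless sample signal is ``blank_od + min(max_od,
    initial_od·2^((t−lag)/DT))`` for t ≥ lag with an initial plateau at
    ``initial_od`` before the lag; blanks carry ``blank_od`` only.  Gaussian
    read noise of scale ``noise_sd`` is added to both and truncated to keep
    every reading positive.  One pair per replicate is returned.
    """
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, params.duration + 1e-9, params.sample_interval)
    truth = _true_corrected_od(t, params)
    out = []
    for rep in range(params.replicates):
        sample_od = params.blank_od + truth
        blank_od = np.full_like(t, params.blank_od)
        if params.noise_sd > 0:
            sample_od = sample_od + rng.normal(0.0, params.noise_sd, t.size)
            blank_od = blank_od + rng.normal(0.0, params.noise_sd, t.size)
        eps = 1e-9
        sample_od = np.maximum(sample_od, eps)
        blank_od = np.maximum(blank_od, eps)
        rep_id = f"r{rep + 1}"
        out.append(
            (
                PlateReaderSeries(f"{strain_id}_{rep_id}_S", t, sample_od,
                                  role="sample", strain_id=strain_id, replicate_id=rep_id),
                PlateReaderSeries(f"{strain_id}_{rep_id}_B", t, blank_od,
                                  role="blank", strain_id=strain_id, replicate_id=rep_id),
            )
        )
    return out


#: growth parameterizations of the five single-tuf strains in rich medium
#: (lag min, doubling time min, max OD600), used as generator ground truth
TABLE_STRAIN_PARAMS: dict[str, dict[str, float]] = {
    "E_coli": {"lag_time": 6.8, "doubling_time": 25.0, "max_od": 1.39},
    "Y_enterocolitica": {"lag_time": 8.2, "doubling_time": 26.3, "max_od": 1.39},
    "V_cholerae": {"lag_time": 300.2, "doubling_time": 41.5, "max_od": 1.38},
    "AnEF1": {"lag_time": 10.8, "doubling_time": 48.4, "max_od": 1.23},
    "P_aeruginosa": {"lag_time": 7.3, "doubling_time": 66.9, "max_od": 1.24},
}


# ---------------------------------------------------------------------------
# induction assays
# ---------------------------------------------------------------------------

@dataclass
class InductionSimParams:
    """Ground truth for a β-gal induction assay.

    The transformed signal is y(t) = max(0, slope·(t − step_time)); noise of
    scale ``noise_sd`` is added on the transformed scale, then the series is
    re-encoded as raw A420/A540 readings (with a slow linear A540 scattering
    drift) that invert exactly through the correction + sqrt transform.
    """

    step_time: float                 # seconds
    accumulation_slope: float        # transformed units / second
    background_a420: float = 0.04
    background_a540: float = 0.02
    noise_sd: float = 0.0
    sample_interval: float = 20.0
    duration: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.step_time < self.duration):
            raise SimulationError("step_time must satisfy 0 < step_time < duration")
        if self.accumulation_slope <= 0:
            raise SimulationError("accumulation_slope must be > 0")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if self.sample_interval <= 0:
            raise SimulationError("sample_interval must be > 0")


def simulate_induction_assay(params: InductionSimParams, strain_id: str = "strain") -> InductionSeries:
    """Simulate raw A420/A540 pairs whose corrected transform is y(t) + noise.

    A540 carries a small linear cell-scattering drift; A420 carries the
    matching 1.75× scattering term plus ``z·|z|`` where z = y(t) + noise, so
    sqrt(max(0, corrA420 − 1.75·corrA540)) returns max(0, z) exactly.
    """
    rng = np.random.default_rng(params.seed)
    t = np.arange(params.sample_interval, params.duration + 1e-9, params.sample_interval)
    y = np.maximum(0.0, params.accumulation_slope * (t - params.step_time))
    z = y + (rng.normal(0.0, params.noise_sd, t.size) if params.noise_sd > 0 else 0.0)
    t0_a420 = params.background_a420 + 0.015     # cells, pre-induction
    t0_a540 = params.background_a540 + 0.010
    scatter = 0.01 * t / params.duration          # slow growth of cell debris signal
    a540 = t0_a540 + scatter
    a420 = t0_a420 + SCATTER_COEFF * scatter + z * np.abs(z)
    return InductionSeries(
        times=t,
        a420=a420,
        a540=a540,
        background_a420=params.background_a420,
        background_a540=params.background_a540,
        t0_a420=t0_a420,
        t0_a540=t0_a540,
        strain_id=strain_id,
    )


# ---------------------------------------------------------------------------
# homolog families
# ---------------------------------------------------------------------------

@dataclass
class FamilySimParams:
    """Ground truth for a homolog family diverged from a common ancestor.

    Each homolog receives a Poisson(distance·length) number of substitution
    events at uniform positions outside the planted columns; every event
    writes a uniformly chosen non-ancestral residue, so a site differs from
    the ancestor iff it was hit at least once and the expected fraction of
    differing sites is exactly 1 − e^(−d) when no columns are planted.
    Planted columns stay ancestral in all viable rows and are mutated in at
    least one nonviable row each.
    """

    n_viable: int
    n_nonviable: int
    target_distances: list[float] = field(default_factory=list)
    length: int = 393
    n_planted_columns: int = 0
    alphabet_size: int = 20
    seed: int = 0
    ensure_exact_recovery: bool = True

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SimulationError("length must be >= 1")
        if self.n_viable < 0 or self.n_nonviable < 0:
            raise SimulationError("sequence counts must be >= 0")
        if not (0 <= self.n_planted_columns <= self.length):
            raise SimulationError("n_planted_columns must lie in [0, length]")
        if self.n_planted_columns and not self.n_nonviable:
            raise SimulationError("planted columns need >= 1 nonviable sequence")
        if not (2 <= self.alphabet_size <= len(AA_ALPHABET)):
            raise SimulationError(f"alphabet_size must lie in [2, {len(AA_ALPHABET)}]")
        n_total = self.n_viable + self.n_nonviable
        if not self.target_distances:
            self.target_distances = [0.1] * n_total
        if len(self.target_distances) != n_total:
            raise SimulationError("one target distance per homolog required")
        if any(d < 0 for d in self.target_distances):
            raise SimulationError("target distances must be >= 0")


@dataclass
class SimulatedFamily:
    alignment: LabeledAlignment
    ancestor: str
    planted_columns: list[int]     # 1-based alignment columns


def _mutate(rng: np.random.Generator, current: str, alphabet: str) -> str:
    choices = [a for a in alphabet if a != current]
    return choices[rng.integers(len(choices))]


def simulate_homolog_family(params: FamilySimParams) -> SimulatedFamily:
    """Evolve viable and nonviable homologs from a random common ancestor.

    Returns the labeled (gap-free) alignment, the ancestor sequence, and the
    exact planted-column set.  With ``ensure_exact_recovery`` (default), any
    background column that would satisfy the discriminating-column rule by
    chance — all viable rows untouched while a nonviable row mutated — has
    the nonviable difference reverted, so the discriminating set equals the
    planted set exactly.
    """
    rng = np.random.default_rng(params.seed)
    alphabet = AA_ALPHABET[: params.alphabet_size]
    L = params.length
    ancestor = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), L))

    planted = sorted(rng.choice(L, size=params.n_planted_columns, replace=False).tolist()) \
        if params.n_planted_columns else []
    planted_set = set(planted)
    background = np.array([i for i in range(L) if i not in planted_set], dtype=int)

    n_total = params.n_viable + params.n_nonviable
    labels = ["viable"] * params.n_viable + ["nonviable"] * params.n_nonviable
    rows: list[list[str]] = []
    for j in range(n_total):
        seq = list(ancestor)
        d = params.target_distances[j]
        if d > 0 and background.size:
            n_events = rng.poisson(d * L)
            hits = background[rng.integers(0, background.size, n_events)]
            for pos in set(hits.tolist()):
                seq[pos] = _mutate(rng, ancestor[pos], alphabet)
        rows.append(seq)

    # plant the discriminating signal: every planted column differs in >= 1
    # nonviable row (viable rows keep the ancestral residue by construction)
    if planted:
        for col in planted:
            k = int(rng.integers(params.n_viable, n_total))
            rows[k][col] = _mutate(rng, ancestor[col], alphabet)
            # optionally let further nonviable rows differ there too
            for k2 in range(params.n_viable, n_total):
                if k2 != k and rng.random() < 0.5:
                    rows[k2][col] = _mutate(rng, ancestor[col], alphabet)

    if params.ensure_exact_recovery and params.n_viable and params.n_nonviable:
        # revert accidental background "discriminating" columns: viable rows
        # all identical there while some nonviable row differs
        for col in background:
            vres = {rows[j][col] for j in range(params.n_viable)}
            if len(vres) != 1:
                continue
            res = next(iter(vres))
            for k in range(params.n_viable, n_total):
                if rows[k][col] != res:
                    rows[k][col] = res

    seqs = [
        ProteinSequence(id=f"{'viable' if lab == 'viable' else 'nonviable'}_{i + 1}",
                        residues="".join(row))
        for i, (row, lab) in enumerate(zip(rows, labels))
    ]
    aln = LabeledAlignment(sequences=seqs, labels=labels)
    return SimulatedFamily(
        alignment=aln,
        ancestor=ancestor,
        planted_columns=[c + 1 for c in planted],
    )


# ---------------------------------------------------------------------------
# toy interactomes
# ---------------------------------------------------------------------------

@dataclass
class NetworkSimParams:
    """Preferential-attachment toy interactome with essentiality labels."""

    n_nodes: int
    attachment_edges: int = 2
    essential_fraction: float = 0.3
    hub_label: str | None = None
    hub_neighbor_essential_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise SimulationError("n_nodes must be >= 2")
        if not (1 <= self.attachment_edges < self.n_nodes):
            raise SimulationError("attachment_edges must lie in [1, n_nodes)")
        if not (0 <= self.essential_fraction <= 1):
            raise SimulationError("essential_fraction must lie in [0, 1]")
        if self.hub_neighbor_essential_fraction is not None and not (
            0 <= self.hub_neighbor_essential_fraction <= 1
        ):
            raise SimulationError("hub_neighbor_essential_fraction must lie in [0, 1]")


def simulate_interactome(params: NetworkSimParams) -> Interactome:
    """Grow a connected scale-free graph and sample essentiality flags.

    Nodes are labeled P0001…; the highest-degree node is renamed to
    ``hub_label`` when given, and its first neighborhood can be enriched in
    essential nodes by ``hub_neighbor_essential_fraction``.
    """
    rng = np.random.default_rng(params.seed)
    g = nx.barabasi_albert_graph(
        params.n_nodes, params.attachment_edges,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    width = max(4, len(str(params.n_nodes)))
    mapping = {i: f"P{i + 1:0{width}d}" for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    if params.hub_label is not None:
        hub = max(sorted(g.nodes), key=lambda n: g.degree[n])
        g = nx.relabel_nodes(g, {hub: params.hub_label})
    for node in g.nodes:
        g.nodes[node]["essential"] = bool(rng.random() < params.essential_fraction)
    if params.hub_label is not None and params.hub_neighbor_essential_fraction is not None:
        for nb in g.neighbors(params.hub_label):
            g.nodes[nb]["essential"] = bool(
                rng.random() < params.hub_neighbor_essential_fraction
            )
    return Interactome(graph=g)
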