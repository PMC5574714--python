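"""File parsing/writing, configuration and the full-pipeline runner.

Readers are strict: malformed records raise with the file, line and field
named rather than being silently coerced.  All report tables are
tab-separated text; alignment columns and residue positions are 1-based in
every report.  Times are minutes in growth tables and seconds in induction
tables — the unit is part of the column name (``time_min`` / ``time_s``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import correlate, growth, network, seqevo, steptime, synthetic

__all__ = [
    "IOError_",
    "PipelineConfig",
    "read_sequences",
    "write_sequences",
    "read_labeled_alignment",
    "read_plate_table",
    "write_plate_table",
    "read_induction_table",
    "read_interactome",
    "write_interactome",
    "read_strain_table",
    "run_pipeline",
]

logger = logging.getLogger("tufkit")


class IOError_(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# sequences and alignments
# ---------------------------------------------------------------------------

_FORMAT_MAP = {"fasta": "fasta", "aligned-fasta": "fasta", "clustal": "clustal"}


def read_sequences(path: str | Path, format: str = "fasta") -> list[seqevo.ProteinSequence]:
    """Read protein sequences; ``aligned-fasta``/``clustal`` enforce equal row lengths."""
    if format not in _FORMAT_MAP:
        raise IOError_(f"{path}: unknown format {format!r}")
    records = list(SeqIO.parse(str(path), _FORMAT_MAP[format]))
    if not records:
        raise IOError_(f"{path}: no sequences found")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise IOError_(f"{path}: duplicate sequence ids {dupes}")
    seqs = [seqevo.ProteinSequence(id=r.id, residues=str(r.seq)) for r in records]
    if format in ("aligned-fasta", "clustal"):
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise IOError_(f"{path}: ragged alignment rows, lengths {sorted(lengths)}")
    return seqs


def write_sequences(seqs: list[seqevo.ProteinSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_labeled_alignment(
    alignment_path: str | Path,
    labels_path: str | Path,
    format: str = "aligned-fasta",
) -> seqevo.LabeledAlignment:
    """Aligned FASTA/Clustal plus a two-column (id, label) table."""
    seqs = read_sequences(alignment_path, format=format)
    labels_df = pd.read_csv(labels_path, sep="\t", header=None, names=["id", "label"],
                            dtype=str, comment="#")
    label_map = dict(zip(labels_df["id"], labels_df["label"]))
    missing = [s.id for s in seqs if s.id not in label_map]
    if missing:
        raise IOError_(f"{labels_path}: no label for sequence(s) {missing}")
    return seqevo.LabeledAlignment(
        sequences=seqs, labels=[label_map[s.id] for s in seqs]
    )


# ---------------------------------------------------------------------------
# plate-reader and induction tables
# ---------------------------------------------------------------------------

PLATE_COLUMNS = ["well", "strain", "replicate", "role", "time_min", "od600"]


def read_plate_table(path: str | Path) -> dict[str, growth.PlateReaderSeries]:
    """Long-format plate table -> one PlateReaderSeries per well.

    Rows are sorted by time within each well; a non-monotone grid after
    sorting (duplicate times) is rejected.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing column(s) {missing}")
    wells: dict[str, growth.PlateReaderSeries] = {}
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_min")
        times = grp["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise IOError_(f"{path}: well {well}: duplicate or non-increasing times")
        roles = grp["role"].unique()
        if len(roles) != 1 or roles[0] not in ("sample", "blank"):
            raise IOError_(f"{path}: well {well}: role must be a single sample|blank value")
        wells[str(well)] = growth.PlateReaderSeries(
            well_id=str(well),
            times=times,
            od600=grp["od600"].to_numpy(dtype=float),
            role=str(roles[0]),
            strain_id=str(grp["strain"].iloc[0]),
            replicate_id=str(grp["replicate"].iloc[0]),
        )
    return wells


def match_blanks(
    wells: dict[str, growth.PlateReaderSeries],
) -> list[tuple[growth.PlateReaderSeries, growth.PlateReaderSeries]]:
    """Pair every sample well with the blank sharing its strain/replicate key."""
    blanks = {(w.strain_id, w.replicate_id): w for w in wells.values() if w.role == "blank"}
    pairs = []
    for w in wells.values():
        if w.role != "sample":
            continue
        key = (w.strain_id, w.replicate_id)
        if key not in blanks:
            raise IOError_(f"sample well {w.well_id}: no blank well for strain/replicate {key}")
        pairs.append((w, blanks[key]))
    return pairs


def write_plate_table(
    pairs: list[tuple[growth.PlateReaderSeries, growth.PlateReaderSeries]],
    path: str | Path,
) -> None:
    rows = []
    for series in (s for pair in pairs for s in pair):
        for t, od in zip(series.times, series.od600):
            rows.append((series.well_id, series.strain_id, series.replicate_id,
                         series.role, t, od))
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_induction_table(path: str | Path, controls_path: str | Path) -> steptime.InductionSeries:
    """Induction table (time_s, a420, a540) plus a control table.

    The control table has rows ``background`` and ``t0`` with a420/a540
    columns.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("time_s", "a420", "a540"):
        if col not in df.columns:
            raise IOError_(f"{path}: missing column {col!r}")
    ctl = pd.read_csv(controls_path, sep=None, engine="python")
    for col in ("kind", "a420", "a540"):
        if col not in ctl.columns:
            raise IOError_(f"{controls_path}: missing column {col!r}")
    ctl = ctl.set_index("kind")
    for kind in ("background", "t0"):
        if kind not in ctl.index:
            raise IOError_(f"{controls_path}: missing control row {kind!r}")
    return steptime.InductionSeries(
        times=df["time_s"].to_numpy(dtype=float),
        a420=df["a420"].to_numpy(dtype=float),
        a540=df["a540"].to_numpy(dtype=float),
        background_a420=float(ctl.loc["background", "a420"]),
        background_a540=float(ctl.loc["background", "a540"]),
        t0_a420=float(ctl.loc["t0", "a420"]),
        t0_a540=float(ctl.loc["t0", "a540"]),
    )


# ---------------------------------------------------------------------------
# interactome tables
# ---------------------------------------------------------------------------

def read_interactome(edges_path: str | Path, nodes_path: str | Path | None = None) -> network.Interactome:
    """Tab-separated edge list (+ optional node attribute table: id, essential 0/1)."""
    edf = pd.read_csv(edges_path, sep="\t", header=None, comment="#",
                      usecols=[0, 1], names=["a", "b"], dtype=str)
    if edf.isna().any().any():
        raise IOError_(f"{edges_path}: malformed edge rows")
    essential: dict[str, bool] = {}
    extra: list[str] = []
    if nodes_path is not None:
        ndf = pd.read_csv(nodes_path, sep="\t", dtype={"id": str})
        for col in ("id", "essential"):
            if col not in ndf.columns:
                raise IOError_(f"{nodes_path}: missing column {col!r}")
        essential = {str(r.id): bool(int(r.essential)) for r in ndf.itertuples()}
        extra = list(essential)
    net = network.Interactome.from_edges(
        list(edf.itertuples(index=False, name=None)), essential=essential, extra_nodes=extra
    )
    if net.n_dropped:
        logger.info("interactome: dropped %d duplicate/self-loop records", net.n_dropped)
    return net


def write_interactome(net: network.Interactome, edges_path: str | Path, nodes_path: str | Path) -> None:
    pd.DataFrame(net.edges).to_csv(edges_path, sep="\t", index=False, header=False)
    pd.DataFrame(
        {"id": net.nodes, "essential": [int(net.is_essential(n)) for n in net.nodes]}
    ).to_csv(nodes_path, sep="\t", index=False)


def read_strain_table(path: str | Path) -> list[correlate.StrainRecord]:
    """Per-strain TSV with any subset of the StrainRecord fields."""
    df = pd.read_csv(path, sep="\t")
    if "strain_id" not in df.columns:
        raise IOError_(f"{path}: missing column 'strain_id'")
    records = []
    bool_fields = {"viable", "tufB_amplified", "ancestral"}
    valid = {f.name for f in dataclasses.fields(correlate.StrainRecord)}
    for row in df.to_dict(orient="records"):
        kwargs = {}
        for k, v in row.items():
            if k not in valid or (isinstance(v, float) and np.isnan(v)):
                continue
            kwargs[k] = bool(int(v)) if k in bool_fields else v
        records.append(correlate.StrainRecord(**kwargs))
    return records


# ---------------------------------------------------------------------------
# pipeline configuration and runner
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Parameters for the all-synthetic end-to-end demonstration pipeline."""

    out_dir: str = "tufkit_run"
    seed: int = 0
    window_points: int = 10
    od_floor: float = 1e-4
    min_fit_points: int = 4
    gap_policy: str = "complete"
    growth_noise_sd: float = 0.005
    growth_replicates: int = 3
    induction_noise_sd: float = 0.005
    family_length: int = 393
    family_planted_columns: int = 12
    network_nodes: int = 200
    network_attachment_edges: int = 2
    essential_fraction: float = 0.3

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - valid
        if unknown:
            raise IOError_(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)


# step-time ground truths for the five strains (seconds); ordered as
# TABLE_STRAIN_PARAMS so faster-growing strains get shorter step times
_STEP_TIMES = {"E_coli": 40.0, "Y_enterocolitica": 45.0, "V_cholerae": 70.0,
               "AnEF1": 80.0, "P_aeruginosa": 90.0}


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage on synthetic inputs and write TSV reports + manifest.

    Stages run in dependency order: growth kinetics → relative fitness;
    induction assays → step times; homolog family → divergence and
    discriminating residues; interactome → centrality and enrichment;
    merge → regressions.  Identical config and seed give identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    reports: dict[str, Path] = {}

    # --- growth kinetics + fitness -------------------------------------
    per_strain: dict[str, list[growth.GrowthParameters]] = {}
    rows = []
    for strain, p in synthetic.TABLE_STRAIN_PARAMS.items():
        params = synthetic.GrowthSimParams(
            **p, noise_sd=config.growth_noise_sd,
            replicates=config.growth_replicates,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        pairs = synthetic.simulate_growth_curve(params, strain_id=strain)
        fits = [growth.analyze_curve(s, b, window_points=config.window_points,
                                     od_floor=config.od_floor) for s, b in pairs]
        per_strain[strain] = fits
        for f in fits:
            rows.append((strain, f.replicate_id, f.lag_time, f.doubling_time, f.max_od))
    logger.info("growth: fitted %d curves for %d strains", len(rows), len(per_strain))
    growth_df = pd.DataFrame(rows, columns=["strain", "replicate", "lag_min",
                                            "doubling_time_min", "max_od600"])
    reports["growth"] = out / "growth_parameters.tsv"
    growth_df.to_csv(reports["growth"], sep="\t", index=False, float_format="%.6g")

    reference = per_strain["E_coli"]
    fitness = {s: growth.relative_fitness(fits, reference) for s, fits in per_strain.items()}
    fit_df = pd.DataFrame(
        [(s, r.fitness, r.reference_mean_dt) for s, r in fitness.items()],
        columns=["strain", "relative_fitness", "reference_mean_dt_min"],
    )
    reports["fitness"] = out / "relative_fitness.tsv"
    fit_df.to_csv(reports["fitness"], sep="\t", index=False, float_format="%.6g")

    # --- step times -----------------------------------------------------
    st_rows = []
    rates: dict[str, float] = {}
    for strain, st in _STEP_TIMES.items():
        params = synthetic.InductionSimParams(
            step_time=st, accumulation_slope=0.002,
            noise_sd=config.induction_noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        series = synthetic.simulate_induction_assay(params, strain_id=strain)
        res = steptime.estimate_step_time(
            steptime.schleif_transform(series), min_fit_points=config.min_fit_points
        )
        rates[strain] = res.synthesis_rate
        st_rows.append((strain, res.step_time, res.synthesis_rate))
    ref_rate = rates["E_coli"]
    st_df = pd.DataFrame(st_rows, columns=["strain", "step_time_s", "synthesis_rate_aa_per_s"])
    st_df["relative_rate"] = st_df["synthesis_rate_aa_per_s"] / ref_rate
    reports["steptime"] = out / "step_times.tsv"
    st_df.to_csv(reports["steptime"], sep="\t", index=False, float_format="%.6g")

    # --- homolog family: divergence + discriminating residues -----------
    strains = list(synthetic.TABLE_STRAIN_PARAMS)
    dists = [0.02, 0.06, 0.18, 0.25, 0.35]
    fam = synthetic.simulate_homolog_family(
        synthetic.FamilySimParams(
            n_viable=len(strains), n_nonviable=6,
            target_distances=dists + [0.5, 0.55, 0.6, 0.65, 0.7, 0.75],
            length=config.family_length,
            n_planted_columns=config.family_planted_columns,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    )
    raw_d = {
        strains[i]: seqevo.poisson_distance(fam.ancestor, fam.alignment.sequences[i],
                                            gap_policy=config.gap_policy).poisson_d
        for i in range(len(strains))
    }
    norm_d = seqevo.normalize_divergence(
        {s: d for s, d in raw_d.items()} | {"_max_nonviable": 0.75}
    )
    report = seqevo.find_discriminating_residues(fam.alignment)
    disc_df = pd.DataFrame({"alignment_column": report.columns})
    reports["discriminating"] = out / "discriminating_columns.tsv"
    disc_df.to_csv(reports["discriminating"], sep="\t", index=False)
    div_df = pd.DataFrame(
        [(s, raw_d[s], norm_d[s]) for s in strains],
        columns=["strain", "poisson_d", "normalized_divergence"],
    )
    reports["divergence"] = out / "divergence.tsv"
    div_df.to_csv(reports["divergence"], sep="\t", index=False, float_format="%.6g")

    # --- interactome ----------------------------------------------------
    net = synthetic.simulate_interactome(
        synthetic.NetworkSimParams(
            n_nodes=config.network_nodes,
            attachment_edges=config.network_attachment_edges,
            essential_fraction=config.essential_fraction,
            hub_label="EFTU", hub_neighbor_essential_fraction=0.8,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    )
    cent = network.degree_centrality(net)
    sub = network.neighbor_subnetwork(net, "EFTU")
    neighbors = [n for n in sub.nodes if n != "EFTU"]
    enrich = network.essentiality_enrichment(neighbors, net)
    net_df = pd.DataFrame(
        {
            "metric": ["hub_degree", "mean_degree", "hub_rank", "neighbor_essential_overlap",
                       "enrichment_p"],
            "value": [cent.degree["EFTU"], cent.mean_degree,
                      cent.ranking.index("EFTU") + 1, enrich.overlap, enrich.p_value],
        }
    )
    reports["network"] = out / "network_connectivity.tsv"
    net_df.to_csv(reports["network"], sep="\t", index=False, float_format="%.6g")

    # --- merge + regressions --------------------------------------------
    records = [
        correlate.StrainRecord(
            strain_id=s,
            fitness=fitness[s].fitness,
            divergence=norm_d[s],
            synthesis_rate=rates[s],
            viable=True,
            ancestral=(s == "AnEF1"),
        )
        for s in strains
    ]
    fits = {
        "fitness_vs_divergence_extant": correlate.fit_records(
            records, "divergence", "fitness", exclude_ancestral=True),
        "fitness_vs_synthesis_rate": correlate.fit_records(
            records, "synthesis_rate", "fitness"),
    }
    corr_df = pd.DataFrame(
        [(name, r.slope, r.intercept, r.r_squared, r.n, r.p_value)
         for name, r in fits.items()],
        columns=["analysis", "slope", "intercept", "r_squared", "n", "p_value"],
    )
    reports["correlations"] = out / "correlations.tsv"
    corr_df.to_csv(reports["correlations"], sep="\t", index=False, float_format="%.10g")

    from . import __version__
    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "tufkit_version": __version__,
        "reports": {k: str(v) for k, v in reports.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    reports["manifest"] = manifest_path
    return reports
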