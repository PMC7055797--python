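"""Readers and writers shared by the simulator, scanner and generator.

Formats: bedGraph / two-column TSV for coverage, BED for duplication
calls, TSV for pileups, trajectories and divergence tables, GFF3 for CDS
annotation, FASTA for references, YAML for scenario configuration and
JSON for run summaries / parameter echoes.  Coordinates are 0-based
half-open everywhere except GFF3, which is converted at the boundary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path
from typing import List, Optional, Sequence, Union

import gffutils
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage_scan import (
    PILEUP_COLUMNS,
    CoverageTrack,
    DivergenceCall,
    DuplicationCall,
    GeneAnnotation,
)
from .growth_dynamics import GrowthParams
from .passage_simulator import PassageProtocol, Scenario, Trajectory
from .strain_model import FitnessScheme, TransitionRates

__all__ = [
    "CoverageFormatError",
    "read_coverage",
    "write_coverage",
    "read_pileup",
    "write_pileup",
    "write_calls",
    "read_calls",
    "write_divergence_table",
    "write_trajectory",
    "read_trajectory",
    "write_run_summary",
    "load_scenario",
    "save_scenario",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "write_params_echo",
    "setup_logging",
]

PathLike = Union[str, Path]


class CoverageFormatError(ValueError):
    """Malformed, unsorted or overlapping coverage input."""


def setup_logging(level: str = "INFO") -> logging.Logger:
    """Configure the package logger to emit machine-readable lines on stderr."""
    logger = logging.getLogger("snapsim")
    logger.setLevel(level.upper())
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    return logger


# ---------------------------------------------------------------------------
# coverage tracks


def read_coverage(path: PathLike, fmt: Optional[str] = None) -> CoverageTrack:
    """Read a per-base coverage track from bedGraph or position/depth TSV.

    bedGraph rows are ``contig  start  end  depth`` (0-based half-open);
    the TSV form is ``position  depth`` with one row per base.  Intervals
    must be sorted and non-overlapping; gaps are filled with depth 0.
    Errors report the offending line number.
    """
    path = Path(path)
    if fmt is None:
        fmt = "bedgraph" if path.suffix.lower() in {".bedgraph", ".bg", ".bed"} else "tsv"

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            rows.append((lineno, fields))
    if not rows:
        raise CoverageFormatError(f"{path}: no data lines")

    if fmt == "bedgraph":
        contigs = {f[0] for _, f in rows}
        if len(contigs) != 1:
            raise CoverageFormatError(
                f"{path}: expected a single contig, found {sorted(contigs)}"
            )
        contig = rows[0][1][0]
        prev_end = 0
        parsed = []
        for lineno, f in rows:
            try:
                start, end, depth = int(f[1]), int(f[2]), float(f[3])
            except (IndexError, ValueError) as err:
                raise CoverageFormatError(f"{path}:{lineno}: malformed bedGraph line") from err
            if end <= start or depth < 0:
                raise CoverageFormatError(f"{path}:{lineno}: invalid interval or depth")
            if start < prev_end:
                raise CoverageFormatError(
                    f"{path}:{lineno}: unsorted or overlapping interval (start {start} < previous end {prev_end})"
                )
            parsed.append((start, end, depth))
            prev_end = end
        depth_arr = np.zeros(prev_end)
        for start, end, depth in parsed:
            depth_arr[start:end] = depth
        return CoverageTrack(contig=contig, depth=depth_arr)

    # two-column TSV: position, depth; contig taken from filename stem
    prev_pos = -1
    positions, depths = [], []
    for lineno, f in rows:
        try:
            pos, depth = int(f[0]), float(f[1])
        except (IndexError, ValueError) as err:
            raise CoverageFormatError(f"{path}:{lineno}: malformed TSV line") from err
        if pos <= prev_pos:
            raise CoverageFormatError(f"{path}:{lineno}: positions must be strictly increasing")
        if depth < 0:
            raise CoverageFormatError(f"{path}:{lineno}: negative depth")
        positions.append(pos)
        depths.append(depth)
        prev_pos = pos
    depth_arr = np.zeros(positions[-1] + 1)
    depth_arr[np.array(positions)] = depths
    return CoverageTrack(contig=path.stem, depth=depth_arr)


def write_coverage(track: CoverageTrack, path: PathLike) -> None:
    """Write a track as run-length-encoded bedGraph."""
    depth = np.asarray(track.depth)
    change = np.nonzero(np.diff(depth))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [depth.size]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            d = depth[s]
            d_str = f"{int(d)}" if float(d).is_integer() else f"{d:g}"
            fh.write(f"{track.contig}\t{s}\t{e}\t{d_str}\n")


# ---------------------------------------------------------------------------
# pileups and calls


def read_pileup(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "allele": str})
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: pileup table missing columns {missing}")
    return df


def write_pileup(pileup: pd.DataFrame, path: PathLike) -> None:
    pileup.to_csv(path, sep="\t", index=False)


def write_calls(calls: Sequence[DuplicationCall], path: PathLike) -> None:
    """Write duplication calls as BED (score = mean ratio x1000, truncated)."""
    ordered = sorted(calls, key=lambda c: (c.contig, c.start))
    with open(path, "w") as fh:
        fh.write("#contig\tstart\tend\tname\tscore\n")
        for i, c in enumerate(ordered, start=1):
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\tdup_{i}\t{int(c.mean_ratio * 1000)}\n")


def read_calls(path: PathLike) -> List[DuplicationCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            contig, start, end, _name, score = line.split("\t")[:5]
            calls.append(
                DuplicationCall(
                    contig=contig,
                    start=int(start),
                    end=int(end),
                    mean_ratio=int(score) / 1000,
                )
            )
    return calls


def write_divergence_table(divs: Sequence[DivergenceCall], path: PathLike) -> None:
    rows = [
        {
            "contig": d.contig,
            "pos": d.pos,
            "ref": d.ref,
            "alt": d.alt,
            "depth": d.depth,
            "fraction": round(d.fraction, 6),
            "effect": d.effect if d.effect is not None else ".",
            "dup_start": d.duplication.start,
            "dup_end": d.duplication.end,
        }
        for d in divs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "contig",
            "pos",
            "ref",
            "alt",
            "depth",
            "fraction",
            "effect",
            "dup_start",
            "dup_end",
        ],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trajectories

_TRAJ_COLUMNS = ["passage", "generations", "wt", "dup", "d1", "d2"]


def write_trajectory(
    trajectory: Trajectory,
    tsv_path: PathLike,
    json_path: Optional[PathLike] = None,
    scenario: Optional[Scenario] = None,
) -> None:
    """Write the per-passage table (counts at 6 significant digits) and,
    optionally, a JSON run summary with outcome and full parameter echo."""
    if len(trajectory) == 0:
        raise ValueError("trajectory is empty")
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(_TRAJ_COLUMNS) + "\n")
        for i in range(len(trajectory)):
            cells = "\t".join(f"{c:.6e}" for c in trajectory.counts[i])
            fh.write(f"{trajectory.passages[i]}\t{trajectory.generations[i]:.6f}\t{cells}\n")
    if json_path is not None:
        write_run_summary(trajectory, json_path, scenario=scenario)


def write_run_summary(
    trajectory: Trajectory, path: PathLike, scenario: Optional[Scenario] = None
) -> None:
    summary = {
        "outcome": trajectory.outcome,
        "fixation_generation": trajectory.fixation_generation,
        "passages": int(len(trajectory)),
        "total_generations": float(trajectory.generations[-1]),
        "seed": trajectory.seed,
        "final_counts": {
            name: float(x)
            for name, x in zip(["wt", "dup", "d1", "d2"], trajectory.counts[-1])
        },
    }
    if scenario is not None:
        summary["scenario"] = scenario_to_dict(scenario)
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_trajectory(path: PathLike) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: trajectory table missing columns {missing}")
    return Trajectory(
        passages=df["passage"].to_numpy(dtype=int),
        generations=df["generations"].to_numpy(dtype=float),
        counts=df[["wt", "dup", "d1", "d2"]].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# scenario configuration (YAML)


def scenario_to_dict(scenario: Scenario) -> dict:
    return {
        "fitness": {
            "wt": scenario.scheme.wt,
            "dup": scenario.scheme.dup,
            "d1": scenario.scheme.d1,
            "d2": scenario.scheme.d2,
        },
        "rates": scenario.rates.to_named(),
        "growth": dataclasses.asdict(scenario.growth),
        "passage": dataclasses.asdict(scenario.protocol),
        "replicates": scenario.replicates,
        "seed": scenario.seed,
    }


def scenario_from_dict(cfg: dict) -> Scenario:
    fitness = cfg.get("fitness", {})
    rates = cfg.get("rates", {})
    growth = cfg.get("growth", {})
    passage = cfg.get("passage", {})
    return Scenario(
        scheme=FitnessScheme(**fitness),
        rates=TransitionRates.from_named(**rates),
        growth=GrowthParams(**growth),
        protocol=PassageProtocol(**passage),
        replicates=int(cfg.get("replicates", 100)),
        seed=int(cfg.get("seed", 0)),
    )


def load_scenario(path: PathLike) -> Scenario:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return scenario_from_dict(cfg)


def save_scenario(scenario: Scenario, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# FASTA / GFF3


def read_fasta(path: PathLike) -> dict:
    """Contig name -> sequence string."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequence: str, contig: str, path: PathLike) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=contig, description="")], str(path), "fasta")


def write_gff(annotations: Sequence[GeneAnnotation], path: PathLike) -> None:
    """Write CDS annotations as GFF3 (1-based inclusive at the boundary)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            fh.write(
                f"{a.contig}\tsnapsim\tgene\t{a.intervals[0][0] + 1}\t{a.intervals[-1][1]}\t.\t"
                f"{a.strand}\t.\tID={a.gene_id}\n"
            )
            for j, (s, e) in enumerate(a.intervals, start=1):
                phase = a.phase if j == 1 else (3 - (sum(b - c for c, b in a.intervals[: j - 1]) - a.phase) % 3) % 3
                fh.write(
                    f"{a.contig}\tsnapsim\tCDS\t{s + 1}\t{e}\t.\t{a.strand}\t{phase}\t"
                    f"ID={a.gene_id}.cds{j};Parent={a.gene_id}\n"
                )


def read_gff(path: PathLike) -> List[GeneAnnotation]:
    """Read CDS features from GFF3, grouped by Parent/ID into genes."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    groups: dict = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", cds.attributes.get("ID", ["gene"]))
        key = parents[0].split(".cds")[0]
        entry = groups.setdefault(
            key, {"contig": cds.seqid, "strand": cds.strand, "intervals": [], "phase": None}
        )
        # GFF3 is 1-based inclusive; convert to 0-based half-open.
        entry["intervals"].append((cds.start - 1, cds.end, cds.frame))
    annotations = []
    for gene_id, entry in groups.items():
        ivals = sorted(entry["intervals"])
        first_frame = ivals[0][2] if entry["strand"] == "+" else ivals[-1][2]
        phase = int(first_frame) if first_frame not in (None, ".") else 0
        annotations.append(
            GeneAnnotation(
                gene_id=gene_id,
                contig=entry["contig"],
                strand=entry["strand"] or "+",
                intervals=[(s, e) for s, e, _ in ivals],
                phase=phase,
            )
        )
    return annotations


# ---------------------------------------------------------------------------
# parameter echo


def write_params_echo(params: dict, path: PathLike) -> None:
    """Full-provenance JSON echo of all effective parameter values."""

    def _default(obj):
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        return str(obj)

    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
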