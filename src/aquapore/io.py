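"""Readers and writers for the package's tabular and sequence dialects.

Traces travel as tidy CSV (oocyte_id, group, condition, time_s, rel_area;
UTF-8, '.' decimal), estimates as flat CSV, comparisons and ground truth
as JSON, sequences as 60-column-wrapped FASTA keyed by the first
whitespace-delimited token of the header.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .hallmarks import SequenceRecord
from .swelling import (
    AssayConstants,
    GroupComparison,
    PermeabilityEstimate,
    SwellingTrace,
    estimate_permeability,
)

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "estimate_traces",
    "write_estimates_csv",
    "read_estimates_csv",
    "comparison_to_json",
    "read_fasta",
    "write_fasta",
]

TRACE_COLUMNS = ["oocyte_id", "group", "condition", "time_s", "rel_area"]


def traces_to_frame(traces: Iterable[SwellingTrace]) -> pd.DataFrame:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "oocyte_id": tr.oocyte_id,
                    "group": tr.group,
                    "condition": tr.condition,
                    "time_s": tr.times,
                    "rel_area": tr.rel_area,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_trace_csv(traces: Iterable[SwellingTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> list[SwellingTrace]:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing columns: {missing}")
    traces = []
    for oid, sub in df.groupby("oocyte_id", sort=False):
        sub = sub.sort_values("time_s")
        traces.append(
            SwellingTrace(
                oocyte_id=str(oid),
                group=str(sub["group"].iloc[0]),
                condition=str(sub["condition"].iloc[0]),
                times=sub["time_s"].to_numpy(dtype=float),
                rel_area=sub["rel_area"].to_numpy(dtype=float),
            )
        )
    return traces


def estimate_traces(
    traces: Sequence[SwellingTrace],
    kind: str,
    constants: AssayConstants = AssayConstants(),
    window_s: float = 60.0,
) -> pd.DataFrame:
    """Estimate Pf or Psol for every trace; one tidy row per oocyte."""
    rows = []
    for tr in traces:
        est = estimate_permeability(tr, kind, constants=constants, window_s=window_s)  # type: ignore[arg-type]
        rows.append(
            {
                "oocyte_id": tr.oocyte_id,
                "group": tr.group,
                "condition": tr.condition,
                "kind": est.kind,
                "slope_per_s": est.slope,
                "value_cm_per_s": est.value,
                "window_s": est.window_s,
                "fit_r2": est.fit_r2,
                "n_points": est.n_points,
            }
        )
    return pd.DataFrame(rows)


def write_estimates_csv(estimates: pd.DataFrame, path: str | Path) -> None:
    estimates.to_csv(path, index=False)


def read_estimates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"kind", "slope_per_s", "value_cm_per_s", "window_s", "fit_r2", "n_points"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"estimates CSV missing columns: {sorted(missing)}")
    return df


def estimates_from_frame(df: pd.DataFrame) -> list[PermeabilityEstimate]:
    return [
        PermeabilityEstimate(
            slope=float(r["slope_per_s"]),
            kind=str(r["kind"]),  # type: ignore[arg-type]
            value=float(r["value_cm_per_s"]),
            window_s=float(r["window_s"]),
            fit_r2=float(r["fit_r2"]),
            n_points=int(r["n_points"]),
        )
        for _, r in df.iterrows()
    ]


def comparison_to_json(comparison: GroupComparison, path: str | Path | None = None) -> str:
    text = json.dumps(dataclasses.asdict(comparison), indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    return [
        SequenceRecord(id=rec.id, alphabet=alphabet, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(rec.residues), id=rec.id, description="")
        for rec in records
    ]
    SeqIO.write(bio, str(path), "fasta")
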