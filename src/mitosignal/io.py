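"""File formats: FASTA, BED6, Ct/cohort CSV, trace TSV, JSON sidecars.

All tabular formats are UTF-8 with a required header row; '.' denotes a
missing value. Parsers are strict and raise with the offending line number.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .respirometry import OxygraphTrace
from .stats import CohortRecord
from .synthetic import GenomePair, NumtTruth

# ---------------------------------------------------------------------------
# FASTA


def write_fasta(path, records: Mapping[str, str]) -> None:
    seqrecs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_pair(out_dir, pair: GenomePair, mito_name: str = "mito") -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mito_path = out_dir / "mito.fa"
    nuc_path = out_dir / "nuclear.fa"
    write_fasta(mito_path, {mito_name: pair.mito})
    write_fasta(nuc_path, dict(pair.nuclear))
    return mito_path, nuc_path


def read_genome_pair(mito_path, nuclear_path) -> GenomePair:
    mito = read_fasta(mito_path)
    if len(mito) != 1:
        raise ValueError(f"{mito_path}: expected exactly one mitochondrial record")
    return GenomePair(mito=next(iter(mito.values())), nuclear=read_fasta(nuclear_path))


# ---------------------------------------------------------------------------
# BED6 (0-based half-open)


def write_bed6(path, intervals: Iterable[tuple[str, int, int, str, float, str]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


def read_bed6(path) -> list[tuple[str, int, int, str, float, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED fields, got {len(parts)}")
            try:
                out.append((parts[0], int(parts[1]), int(parts[2]), parts[3], float(parts[4]), parts[5]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def numt_truth_to_bed(truths: Sequence[NumtTruth]):
    for i, t in enumerate(truths):
        yield (t.contig_id, t.start, t.end, f"numt{i + 1}:mito{t.mito_start}-{t.mito_end}", t.divergence, t.strand)


# ---------------------------------------------------------------------------
# Ct tables / cohort sheets (CSV)

CT_COLUMNS = ["animal_id", "group", "timepoint", "gene", "replicate", "ct"]
COHORT_COLUMNS = ["animal_id", "group", "delta_rq", "post_resp", "endpoint", "sham_mean"]


def write_ct_table(path, table: pd.DataFrame) -> None:
    table[CT_COLUMNS].to_csv(path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, na_values=["."])
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}:1: missing required columns {missing}")
    if table["ct"].isna().any():
        row = int(table.index[table["ct"].isna()][0])
        raise ValueError(f"{path}:{row + 2}: missing ct value")  # +2: header + 1-based
    return table


def write_cohort(path, records: Sequence[CohortRecord]) -> None:
    rows = [
        (r.animal_id, r.group, r.delta_rq, r.post_resp, r.endpoint, r.sham_mean) for r in records
    ]
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort(path) -> list[CohortRecord]:
    df = pd.read_csv(path, na_values=["."])
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}:1: missing required columns {missing}")
    bad = df.index[df[["delta_rq", "post_resp", "sham_mean"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}:{int(bad[0]) + 2}: missing numeric value")
    return [
        CohortRecord(
            animal_id=str(r.animal_id),
            group=str(r.group),
            delta_rq=float(r.delta_rq),
            post_resp=float(r.post_resp),
            sham_mean=float(r.sham_mean),
            endpoint=str(r.endpoint),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# oxygraph traces (TSV: time_s, o2_uM, event; '.' = no event)


def write_trace(path, trace: OxygraphTrace) -> None:
    labels = ["."] * trace.time.size
    for t, lab in trace.events:  # attach each event to its nearest sample
        labels[int(np.argmin(np.abs(trace.time - t)))] = lab
    with open(path, "w") as fh:
        fh.write("time_s\to2_uM\tevent\n")
        for t, o2, label in zip(trace.time, trace.o2, labels):
            fh.write(f"{t:.6g}\t{o2:.6f}\t{label}\n")


def read_trace(path, sample_conc: float, temperature: float = 37.0, solubility_factor: float = 0.92) -> OxygraphTrace:
    times, o2s, events = [], [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["time_s", "o2_uM", "event"]:
            raise ValueError(f"{path}:1: expected header time_s\\to2_uM\\tevent")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            try:
                t, o2 = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            times.append(t)
            o2s.append(o2)
            if parts[2] != ".":
                events.append((t, parts[2]))
    return OxygraphTrace(
        time=np.asarray(times),
        o2=np.asarray(o2s),
        events=tuple(events),
        sample_conc=sample_conc,
        temperature=temperature,
        solubility_factor=solubility_factor,
    )


# ---------------------------------------------------------------------------
# JSON sidecars


def config_hash(config: Mapping) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_sidecar(path, payload: Mapping, config: Mapping, seed: int | None) -> None:
    doc = {"config_hash": config_hash(config), "seed": seed, **payload}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
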