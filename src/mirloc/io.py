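"""File formats: FASTA, Vienna dot-bracket files, TSV tables, reports.

All machine-readable outputs start with provenance comment lines
(tool/schema versions, seed, engine) so a run can be reproduced from its
artifacts alone. Coordinates in every TSV are 1-based inclusive.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .datasets import Annotation
from .errors import DataError, DuplicateId
from .features import SCHEMA, SCHEMA_VERSION
from .locate import Prediction
from .structure import PreMiRNA, normalize_sequence


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered {id: normalized RNA sequence}; ids must be unique."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise DuplicateId(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = normalize_sequence(str(rec.seq))
    return records


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


_VIENNA_MFE = re.compile(r"^([().]+)\s*\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def read_structures(path: str | Path) -> dict[str, tuple[str, str, float]]:
    """Vienna dot-bracket file: {id: (sequence, structure, mfe)}.

    Expected record layout: a '>' header, the sequence line, then the
    structure line with a trailing "(mfe)" as printed by RNAfold.
    """
    out: dict[str, tuple[str, str, float]] = {}
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise DataError(f"{path}: expected a '>' header at line {i + 1}")
        name = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise DataError(f"{path}: truncated record {name!r}")
        seq = normalize_sequence(lines[i + 1])
        m = _VIENNA_MFE.match(lines[i + 2])
        if m:
            structure, mfe = m.group(1), float(m.group(2))
        elif set(lines[i + 2]) <= set("()."):
            structure, mfe = lines[i + 2], 0.0
        else:
            raise DataError(f"{path}: malformed structure line for {name!r}")
        if name in out:
            raise DuplicateId(f"duplicate structure id {name!r} in {path}")
        out[name] = (seq, structure, mfe)
        i += 3
    return out


def premirnas_from_structures(path: str | Path) -> dict[str, PreMiRNA]:
    return {
        name: PreMiRNA.from_dotbracket(name, seq, db, mfe=mfe, engine="precomputed")
        for name, (seq, db, mfe) in read_structures(path).items()
    }


# --------------------------------------------------------------------------
# annotations TSV (two dialects: sequence-based or coordinate-based)
# --------------------------------------------------------------------------


def read_annotations(path: str | Path) -> list[Annotation]:
    """Annotations TSV with header 'premirna_id<TAB>mirna_seq' or
    'premirna_id<TAB>start<TAB>end' (1-based inclusive coordinates)."""
    lines = [
        ln.rstrip("\n")
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise DataError(f"{path}: empty annotations file")
    header = lines[0].split("\t")
    anns: list[Annotation] = []
    if header[:2] == ["premirna_id", "mirna_seq"]:
        for ln in lines[1:]:
            cols = ln.split("\t")
            anns.append(Annotation(premirna_id=cols[0], mature_seq=cols[1]))
    elif header[:3] == ["premirna_id", "start", "end"]:
        for ln in lines[1:]:
            cols = ln.split("\t")
            start1, end1 = int(cols[1]), int(cols[2])
            if start1 < 1 or end1 < start1:
                raise DataError(f"{path}: bad 1-based interval {start1}-{end1}")
            anns.append(Annotation(premirna_id=cols[0], start=start1 - 1, end=end1))
    else:
        raise DataError(
            f"{path}: header must declare (premirna_id, mirna_seq) or "
            f"(premirna_id, start, end); got {header!r}"
        )
    return anns


def write_annotations(anns: list[Annotation], path: str | Path) -> None:
    """Write coordinate-dialect annotations (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("premirna_id\tstart\tend\n")
        for a in anns:
            fh.write(f"{a.premirna_id}\t{a.start + 1}\t{a.end}\n")


# --------------------------------------------------------------------------
# report writers
# --------------------------------------------------------------------------


def provenance_lines(seed: int | None = None, engine: str | None = None) -> list[str]:
    out = [f"#tool=mirloc-{__version__}", f"#schema={SCHEMA_VERSION}"]
    if seed is not None:
        out.append(f"#seed={seed}")
    if engine is not None:
        out.append(f"#engine={engine}")
    return out


def write_features_tsv(
    X: np.ndarray,
    sample_ids: list[str],
    labels: list[str],
    path: str | Path,
    seed: int | None = None,
    engine: str | None = None,
) -> None:
    """Schema-ordered feature table: sample_id, label, then 440 named columns."""
    with open(path, "w") as fh:
        for ln in provenance_lines(seed, engine):
            fh.write(ln + "\n")
        fh.write("sample_id\tlabel\t" + "\t".join(SCHEMA.names) + "\n")
        for sid, lab, row in zip(sample_ids, labels, X):
            fh.write(sid + "\t" + lab + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def write_predictions_tsv(
    predictions: list[Prediction | tuple[str, str]],
    path: str | Path,
    seed: int | None = None,
    engine: str | None = None,
) -> None:
    """One row per pre-miRNA; failures appear as NoPrediction rows."""
    cols = [
        "premirna_id",
        "mirna_seq",
        "start",
        "end",
        "arm",
        "passenger_seq",
        "passenger_start",
        "passenger_end",
        "score",
        "summed_score",
    ]
    with open(path, "w") as fh:
        for ln in provenance_lines(seed, engine):
            fh.write(ln + "\n")
        fh.write("\t".join(cols) + "\n")
        for p in predictions:
            if isinstance(p, Prediction):
                fh.write(
                    f"{p.premirna_id}\t{p.mature_seq}\t{p.start}\t{p.end}\t{p.arm}\t"
                    f"{p.passenger_seq}\t{p.passenger_start}\t{p.passenger_end}\t"
                    f"{p.score:.6f}\t{p.summed_score:.6f}\n"
                )
            else:  # (id, reason)
                fh.write(f"{p[0]}\tNoPrediction:{p[1]}\t" + "\t".join(["NA"] * 8) + "\n")


def read_predictions_tsv(path: str | Path) -> dict[str, tuple[int, int]]:
    """{premirna_id: (start, end)} for successful prediction rows."""
    out: dict[str, tuple[int, int]] = {}
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln and not ln.startswith("#")
    ]
    header = lines[0].split("\t")
    i_id, i_s, i_e = header.index("premirna_id"), header.index("start"), header.index("end")
    for ln in lines[1:]:
        cols = ln.split("\t")
        if cols[i_s] == "NA" or cols[i_s].startswith("NoPrediction"):
            continue
        out[cols[i_id]] = (int(cols[i_s]), int(cols[i_e]))
    return out


def write_evaluation_tsv(
    start_curve: np.ndarray,
    end_curve: np.ndarray,
    path: str | Path,
    seed: int | None = None,
) -> None:
    with open(path, "w") as fh:
        for ln in provenance_lines(seed):
            fh.write(ln + "\n")
        fh.write("d\tstart_freq\tend_freq\n")
        for d, (s, e) in enumerate(zip(start_curve, end_curve)):
            fh.write(f"{d}\t{s:.6f}\t{e:.6f}\n")
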