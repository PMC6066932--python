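"""Sequence I/O and the coding-sequence quality filter.

A gene passes QC iff it is longer than 30 nt (strict), its length is
divisible by 3, it begins with a permitted start codon, ends with a stop
codon, contains no internal stop and no ambiguous bases. The criteria are
checked in that documented order and a failing record carries exactly the
first reason that failed, so report counts sum to the number of failures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

from Bio import SeqIO

from .code import STOP, GeneticCode, rna

logger = logging.getLogger(__name__)

#: ordered QC criteria; each failing record carries the first that fails
QC_REASONS = (
    "too_short",
    "not_codon_multiple",
    "no_start_codon",
    "no_stop_codon",
    "internal_stop",
    "ambiguous",
)


@dataclass(frozen=True)
class GeneRecord:
    id: str
    seq: str  # DNA alphabet, uppercase
    qc_status: str = "unchecked"  # "pass" | "fail:<reason>" | "unchecked"


def read_cds_fasta(path: str | Path) -> list[GeneRecord]:
    """Load nucleotide CDS records from FASTA, in file order.

    Duplicate ids are an error; an empty file is an error. Sequence content
    is not validated here (QC flags ambiguous symbols per record).
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(GeneRecord(id=rec.id, seq=str(rec.seq).upper().replace("U", "T")))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def _qc_reason(seq: str, code: GeneticCode) -> str | None:
    if len(seq) <= 30:
        return "too_short"
    if len(seq) % 3 != 0:
        return "not_codon_multiple"
    s = rna(seq)
    start, stop = s[:3], s[-3:]
    stops = code.stop_codons
    if start not in code.start_codons:
        return "no_start_codon"
    if stop not in stops:
        return "no_stop_codon"
    internal = [s[i : i + 3] for i in range(0, len(s) - 3, 3)]
    if any(c in stops for c in internal):
        return "internal_stop"
    if set(s) - set("ACGU"):
        return "ambiguous"
    return None


def qc_filter(
    records: list[GeneRecord],
    code: GeneticCode,
    min_genes: int = 500,
) -> tuple[list[GeneRecord], dict]:
    """Apply the gene QC filter; returns (passing records, report).

    The report counts failures per reason; a warning is raised (and
    ``report["sufficient"]`` set False) when fewer than ``min_genes`` genes
    pass — the inclusion criterion used for genome-wide fits.
    """
    passing = []
    counts = {r: 0 for r in QC_REASONS}
    checked = []
    for rec in records:
        reason = _qc_reason(rec.seq, code)
        if reason is None:
            rec = replace(rec, qc_status="pass")
            passing.append(rec)
        else:
            rec = replace(rec, qc_status=f"fail:{reason}")
            counts[reason] += 1
        checked.append(rec)
    report = {
        "n_input": len(records),
        "n_pass": len(passing),
        "failures": counts,
        "sufficient": len(passing) >= min_genes,
        "min_genes": min_genes,
        "records": checked,
    }
    if not report["sufficient"]:
        logger.warning(
            "only %d gene(s) pass QC (threshold %d)", len(passing), min_genes
        )
    return passing, report


def write_qc_report(report: dict, path: str | Path) -> None:
    lines = ["record\tstatus"]
    for rec in report["records"]:
        lines.append(f"{rec.id}\t{rec.qc_status}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> dict:
    """Read a key-value config file (``key = value`` lines, '#' comments).

    Recognized keys include wobble penalties (s_gu, s_ic, s_ia, s_ug, s_uu,
    s_uc), cost_metric, min_genes and seed; values are parsed as float/int
    where possible and otherwise kept as strings.
    """
    out: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        value = value.strip()
        try:
            out[key.strip()] = int(value)
        except ValueError:
            try:
                out[key.strip()] = float(value)
            except ValueError:
                out[key.strip()] = value
    return out


def write_fasta(records: list[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")
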