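"""Reading and writing assay tables and chain FASTA files.

The assay table is a CSV/TSV with one row per measured data point:
``id, hc1, lc1, hc2, lc2, concentration_nM, coating, fold_over_control``
(empty cells denote absent chains).  Rows are validated, chains
canonicalized, binary labels derived from the fold-over-control threshold,
and duplicates on the uniqueness key (sequence set, concentration, coating)
collapsed with a log message.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from .errors import SchemaError, ValidationError
from .records import AntibodyRecord, AssayPoint, CHAIN_SLOTS, canonicalize_chains
from .featurize import encode_label

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "id", "hc1", "lc1", "hc2", "lc2",
    "concentration_nM", "coating", "fold_over_control",
)


def _sniff_delimiter(path: Path) -> str:
    head = path.read_text(encoding="utf-8").splitlines()[0]
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def read_assay_table(path, dialect: Optional[str] = None,
                     canonicalize: bool = True) -> list[AssayPoint]:
    """Parse an assay CSV/TSV into validated, deduplicated assay points."""
    path = Path(path)
    delim = {"csv": ",", "tsv": "\t"}.get(dialect) or _sniff_delimiter(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        missing = set(REQUIRED_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(
                f"{path.name}: missing required columns {sorted(missing)}"
            )
        points: list[AssayPoint] = []
        bad_ids: list[str] = []
        for row in reader:
            try:
                points.append(_row_to_point(row, canonicalize))
            except ValidationError as exc:
                bad_ids.append(row.get("id", "?"))
                logger.error("row rejected: %s", exc)
        if bad_ids:
            raise ValidationError(
                f"{path.name}: {len(bad_ids)} invalid record(s): {bad_ids}"
            )
    return deduplicate_points(points)


def _row_to_point(row: dict, canonicalize: bool) -> AssayPoint:
    record = AntibodyRecord(
        id=row["id"].strip(),
        hc1=row["hc1"].strip().upper() or None,
        lc1=row["lc1"].strip().upper() or None,
        hc2=row["hc2"].strip().upper() or None,
        lc2=row["lc2"].strip().upper() or None,
        format_label=row.get("format_label", "unknown").strip() or "unknown",
    )
    if record.hc1 is None:
        raise ValidationError(f"record {record.id!r}: hc1 must be non-empty")
    if canonicalize:
        record = canonicalize_chains(record)
    else:
        record = record.validate()
    try:
        conc = float(row["concentration_nM"])
        fold = float(row["fold_over_control"])
    except ValueError as exc:
        raise ValidationError(
            f"record {record.id!r}: non-numeric concentration or fold"
        ) from exc
    if conc <= 0:
        raise ValidationError(
            f"record {record.id!r}: concentration must be positive, got {conc}"
        )
    coating = row["coating"].strip().upper()
    if coating not in ("BVP", "BSA"):
        raise ValidationError(
            f"record {record.id!r}: unknown coating {row['coating']!r}"
        )
    return AssayPoint(
        antibody=record,
        concentration_nM=conc,
        coating=coating,
        fold_over_control=fold,
        label=encode_label(fold),
    )


def deduplicate_points(points: Iterable[AssayPoint]) -> list[AssayPoint]:
    """Keep the first point per (sequence set, concentration, coating)."""
    seen: dict[tuple, AssayPoint] = {}
    for p in points:
        key = p.uniqueness_key()
        if key in seen:
            logger.info(
                "duplicate data point for %s at %.4g nM on %s dropped",
                p.antibody.id, p.concentration_nM, p.coating,
            )
            continue
        seen[key] = p
    return list(seen.values())


def write_assay_table(points: Iterable[AssayPoint], path,
                      dialect: str = "csv") -> None:
    path = Path(path)
    delim = "\t" if dialect == "tsv" else ","
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(REQUIRED_COLUMNS + ("format_label",))
        for p in points:
            rec = p.antibody
            writer.writerow(
                [rec.id, rec.hc1 or "", rec.lc1 or "", rec.hc2 or "",
                 rec.lc2 or "", repr(p.concentration_nM), p.coating,
                 repr(p.fold_over_control), rec.format_label]
            )


def read_chain_fasta(path) -> list[AntibodyRecord]:
    """Read chains from FASTA with ``id|chain_slot`` headers into records."""
    by_id: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for seq_record in SeqIO.parse(str(path), "fasta"):
        try:
            ab_id, slot = seq_record.id.rsplit("|", 1)
        except ValueError as exc:
            raise ValidationError(
                f"FASTA header {seq_record.id!r} is not of the form id|chain_slot"
            ) from exc
        slot = slot.lower()
        if slot not in CHAIN_SLOTS:
            raise ValidationError(
                f"FASTA header {seq_record.id!r}: unknown chain slot {slot!r}"
            )
        if ab_id not in by_id:
            by_id[ab_id] = {}
            order.append(ab_id)
        by_id[ab_id][slot] = str(seq_record.seq).upper()
    records = []
    for ab_id in order:
        chains = by_id[ab_id]
        if "hc1" not in chains:
            raise ValidationError(f"record {ab_id!r}: FASTA provides no hc1 chain")
        records.append(AntibodyRecord(id=ab_id, **chains).validate())
    return records


def export_domain_sets_json(domain_sets: dict, path) -> None:
    """Write {antibody id -> VariableDomainSet} to a JSON file."""
    payload = {k: v.to_json_dict() for k, v in domain_sets.items()}
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def import_domain_sets_json(path) -> dict:
    from .records import VariableDomainSet

    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    return {k: VariableDomainSet.from_json_dict(v) for k, v in raw.items()}
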