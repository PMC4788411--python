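"""GenBank CDS extraction and FASTA I/O.

Extraction walks the CDS features of a GenBank record (joins and
complements resolved by Biopython's location machinery, so spliced,
strand-corrected nucleotide sequences come out), applies a configurable
acceptance policy, and returns clean :class:`~plastidkit.codon_stats.CdsRecord`
objects plus a per-feature report of what was kept or dropped and why.

Plastomes carry a large inverted repeat; genes inside it appear twice in the
annotation.  By default such duplicates (same gene name, identical sequence)
are counted once so they do not double-weight a codon-usage table.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon_stats import (
    CdsRecord,
    DEFAULT_GENETIC_CODE,
    STOP_SYMBOL,
    translation_map,
)
from .errors import PlastidkitError


@dataclasses.dataclass(frozen=True)
class CdsExtractionPolicy:
    """Acceptance rules for CDS features pulled from a GenBank record."""

    require_mod3: bool = True
    allow_internal_stops: bool = False
    dedupe_inverted_repeat: bool = True
    min_length_codons: int = 2
    exclude_pseudo: bool = True

    def __post_init__(self) -> None:
        if self.min_length_codons < 2:
            raise PlastidkitError("min_length_codons must be >= 2")


def _feature_name(feature, index: int) -> str:
    for key in ("gene", "locus_tag", "protein_id", "product"):
        if key in feature.qualifiers:
            return str(feature.qualifiers[key][0])
    return f"cds_{index}"


def extract_cds(
    genbank,
    policy: CdsExtractionPolicy | None = None,
    genetic_code_id: int = DEFAULT_GENETIC_CODE,
) -> tuple[list[CdsRecord], pd.DataFrame]:
    """Extract CDS records from a GenBank record or flat-file path.

    Returns ``(records, report)``.  The report has one row per CDS feature
    with columns ``name, start, end, strand, n_codons, status, reason``;
    coordinates are 1-based inclusive, as printed in GenBank flat files
    (internally Biopython's 0-based half-open locations are used and
    converted on output).  Features violating the policy are excluded and
    logged, never fatal; an unparseable file raises.
    """
    policy = policy or CdsExtractionPolicy()
    if isinstance(genbank, (str, Path)):
        try:
            record = SeqIO.read(str(genbank), "genbank")
        except Exception as exc:  # noqa: BLE001 - normalize parser errors
            raise PlastidkitError(f"cannot parse GenBank file {genbank}: {exc}")
    else:
        record = genbank

    tmap = translation_map(genetic_code_id)
    accepted: list[CdsRecord] = []
    rows: list[dict] = []
    seen: set[tuple[str, str]] = set()
    features = [f for f in record.features if f.type == "CDS"]
    for i, feature in enumerate(features):
        name = _feature_name(feature, i)
        loc = feature.location
        row = {
            "name": name,
            "start": int(loc.start) + 1,  # 1-based inclusive
            "end": int(loc.end),
            "strand": int(loc.strand or 1),
            "n_codons": None,
            "status": "accepted",
            "reason": "",
        }

        def reject(reason: str) -> None:
            row["status"] = "rejected"
            row["reason"] = reason
            rows.append(row)

        if policy.exclude_pseudo and "pseudo" in feature.qualifiers:
            reject("pseudo")
            continue
        seq = str(feature.extract(record.seq)).upper()
        if policy.require_mod3 and (len(seq) == 0 or len(seq) % 3 != 0):
            reject(f"length {len(seq)} not a multiple of 3")
            continue
        if set(seq) - set("ACGT"):
            reject("non-ACGT characters")
            continue
        n_codons = len(seq) // 3
        row["n_codons"] = n_codons
        if n_codons < policy.min_length_codons:
            reject(f"shorter than {policy.min_length_codons} codons")
            continue
        codons = [seq[j : j + 3] for j in range(0, len(seq), 3)]
        internal = [c for c in codons[:-1] if tmap[c] == STOP_SYMBOL]
        if internal and not policy.allow_internal_stops:
            reject("internal stop codon")
            continue
        key = (name, seq)
        if policy.dedupe_inverted_repeat and key in seen:
            reject("inverted-repeat duplicate")
            continue
        seen.add(key)
        accepted.append(CdsRecord(id=name, sequence=seq))
        rows.append(row)
    report = pd.DataFrame(
        rows,
        columns=["name", "start", "end", "strand", "n_codons", "status", "reason"],
    )
    return accepted, report


def read_fasta(path) -> list[CdsRecord]:
    """Read CDS records from FASTA; sequences are upper-cased on read."""
    records: list[CdsRecord] = []
    ids: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise PlastidkitError(f"duplicate FASTA id {rec.id!r}")
        ids.add(rec.id)
        records.append(CdsRecord(id=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(records: Sequence[CdsRecord], path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def write_extraction_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
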