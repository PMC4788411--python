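"""Codon-usage tables and per-gene codon diagnostics.

The central object is the :class:`CodonUsageTable`: per-triplet counts over a
reference CDS set together with each triplet's frequency *among its
synonyms*.  Against such a table a gene can be scored for

* **GC3** — the fraction of codons whose third base is G or C, the standard
  proxy for adaptation to an AT-rich genome such as a liverwort plastome;
* **optimal codons** — the most frequently used triplet within its synonym
  family in the reference set;
* **rare codons** — triplets with a synonym-relative frequency ≤ 10 %
  (boundary inclusive) in the reference set;
* **mean codon frequency difference** — the average absolute gap between the
  gene's own synonym-relative codon frequencies and the reference table's;
* **synonymous change accounting** — how many codons differ between two
  synonymous recodings of the same protein, overall and per segment.

Per-gene statistics include the stop codon when the sequence carries one: a
239-residue reporter plus terminator is counted as 240 codons.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from functools import lru_cache
from typing import Mapping, Sequence

from Bio.Data import CodonTable

from .errors import AlphabetError, FrameError, NonSynonymousError, PlastidkitError

BASES = "ACGT"
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)
STOP_SYMBOL = "*"

#: default genetic code: NCBI translation table 11 (bacterial/plastid)
DEFAULT_GENETIC_CODE = 11

#: synonym-relative frequency at or below which a codon is "rare"
RARE_THRESHOLD = 0.10

#: variants of the mean codon frequency difference statistic
MEAN_FREQ_DIFF_VARIANTS = ("position", "triplet_uniform", "gene_present", "deficit")


@lru_cache(maxsize=None)
def translation_map(genetic_code_id: int = DEFAULT_GENETIC_CODE) -> dict[str, str]:
    """Map each of the 64 triplets to its amino acid ('*' for stops)."""
    table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    out = dict(table.forward_table)
    for codon in table.stop_codons:
        out[codon] = STOP_SYMBOL
    return out


@lru_cache(maxsize=None)
def synonym_families(
    genetic_code_id: int = DEFAULT_GENETIC_CODE,
) -> dict[str, tuple[str, ...]]:
    """Amino acid (or '*') -> lexicographically sorted tuple of its codons."""
    fams: dict[str, list[str]] = {}
    for codon, aa in translation_map(genetic_code_id).items():
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(codons)) for aa, codons in fams.items()}


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    if len(seq) == 0 or len(seq) % 3 != 0:
        raise FrameError(
            f"sequence length {len(seq)} is not a positive multiple of 3"
        )
    bad = set(seq) - set(BASES)
    if bad:
        raise AlphabetError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return seq


@dataclasses.dataclass(frozen=True)
class CdsRecord:
    """A coding sequence: identifier plus an in-frame ACGT nucleotide string.

    Input is upper-cased on construction; a length that is not a positive
    multiple of three raises :class:`FrameError`, any non-ACGT symbol raises
    :class:`AlphabetError` (no silent skipping of ambiguity codes — every
    downstream statistic is count-exact).
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_sequence(self.sequence))

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    @property
    def codons(self) -> tuple[str, ...]:
        s = self.sequence
        return tuple(s[i : i + 3] for i in range(0, len(s), 3))

    def translate(self, genetic_code_id: int = DEFAULT_GENETIC_CODE) -> str:
        tmap = translation_map(genetic_code_id)
        return "".join(tmap[c] for c in self.codons)


def gc3(cds: CdsRecord) -> float:
    """Fraction of codons whose third base is G or C (stop codon included)."""
    third = cds.sequence[2::3]
    return sum(b in "GC" for b in third) / cds.n_codons


@dataclasses.dataclass(frozen=True)
class CodonUsageTable:
    """Per-triplet counts and synonym-relative frequencies of a CDS set.

    ``freq_among_synonyms[c] = count(c) / count(family of c)``; families with
    zero observations get frequency 0 for every member and are listed in
    ``unobserved_families``.  Families whose maximum frequency is attained by
    more than one codon are listed in ``tied_families``; the designated
    optimal codon is then the lexicographically first of the tied maxima.
    """

    genetic_code_id: int
    counts: Mapping[str, int]
    freq_among_synonyms: Mapping[str, float]
    n_cds: int
    include_stops: bool
    unobserved_families: frozenset[str] = frozenset()
    tied_families: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if set(self.counts) != set(ALL_CODONS):
            raise PlastidkitError("counts must cover exactly the 64 triplets")

    # -- family helpers ----------------------------------------------------
    def family_of(self, codon: str) -> str:
        return translation_map(self.genetic_code_id)[codon]

    def family_codons(self, aa: str) -> tuple[str, ...]:
        return synonym_families(self.genetic_code_id)[aa]

    def optimal_codon(self, aa: str) -> str:
        """The most frequent codon of the family; lexicographic tie-break."""
        members = self.family_codons(aa)
        best = max(self.freq_among_synonyms[c] for c in members)
        return next(c for c in sorted(members) if self.freq_among_synonyms[c] == best)

    # -- classification ----------------------------------------------------
    def classify(self, codon: str) -> str:
        return classify_codon(codon, self)

    def is_optimal(self, codon: str) -> bool:
        return self.classify(codon) == "optimal"

    def is_rare(self, codon: str) -> bool:
        return self.classify(codon) == "rare"

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write codon, amino_acid, count, freq (4 dp), is_optimal, is_rare."""
        lines = [
            f"# genetic_code_id={self.genetic_code_id}",
            f"# n_cds={self.n_cds}",
            f"# include_stops={self.include_stops}",
            "codon\tamino_acid\tcount\tfreq_among_synonyms\tis_optimal\tis_rare",
        ]
        for codon in ALL_CODONS:
            lines.append(
                "\t".join(
                    (
                        codon,
                        self.family_of(codon),
                        str(self.counts[codon]),
                        f"{self.freq_among_synonyms[codon]:.4f}",
                        str(self.is_optimal(codon)),
                        str(self.is_rare(codon)),
                    )
                )
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "CodonUsageTable":
        """Rebuild a table from :meth:`to_tsv` output.

        Counts are exact integers, so synonym-relative frequencies are
        recomputed from them rather than re-read at 4-decimal precision; the
        round trip is lossless.
        """
        meta: dict[str, str] = {}
        counts: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key.strip()] = val.strip()
                    continue
                if not line or line.startswith("codon\t"):
                    continue
                codon, _aa, count, *_ = line.split("\t")
                counts[codon] = int(count)
        return cls.from_counts(
            counts,
            genetic_code_id=int(meta.get("genetic_code_id", DEFAULT_GENETIC_CODE)),
            n_cds=int(meta.get("n_cds", 0)),
            include_stops=meta.get("include_stops", "True") == "True",
        )

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, int],
        genetic_code_id: int = DEFAULT_GENETIC_CODE,
        n_cds: int = 0,
        include_stops: bool = True,
    ) -> "CodonUsageTable":
        full = {c: int(counts.get(c, 0)) for c in ALL_CODONS}
        if any(v < 0 for v in full.values()):
            raise PlastidkitError("codon counts must be non-negative")
        freqs: dict[str, float] = {}
        unobserved: set[str] = set()
        tied: set[str] = set()
        for aa, members in synonym_families(genetic_code_id).items():
            fam_total = sum(full[c] for c in members)
            if fam_total == 0:
                unobserved.add(aa)
                for c in members:
                    freqs[c] = 0.0
                continue
            for c in members:
                freqs[c] = full[c] / fam_total
            best = max(freqs[c] for c in members)
            if sum(freqs[c] == best for c in members) > 1:
                tied.add(aa)
        return cls(
            genetic_code_id=genetic_code_id,
            counts=full,
            freq_among_synonyms=freqs,
            n_cds=n_cds,
            include_stops=include_stops,
            unobserved_families=frozenset(unobserved),
            tied_families=frozenset(tied),
        )


def build_usage_table(
    cds_set: Sequence[CdsRecord],
    genetic_code_id: int = DEFAULT_GENETIC_CODE,
    include_stops: bool = True,
) -> CodonUsageTable:
    """Aggregate codon counts over a CDS set into a usage table.

    With ``include_stops=False`` stop triplets are not counted (the stop
    family is then flagged unobserved unless some sequence uses a stop
    triplet in a sense position, which cannot happen for clean CDS).
    """
    if len(cds_set) == 0:
        raise PlastidkitError("cannot build a usage table from an empty CDS set")
    tmap = translation_map(genetic_code_id)
    counter: Counter[str] = Counter()
    for cds in cds_set:
        for codon in cds.codons:
            if not include_stops and tmap[codon] == STOP_SYMBOL:
                continue
            counter[codon] += 1
    return CodonUsageTable.from_counts(
        counter,
        genetic_code_id=genetic_code_id,
        n_cds=len(cds_set),
        include_stops=include_stops,
    )


def classify_codon(triplet: str, table: CodonUsageTable) -> str:
    """Classify a triplet as ``optimal``, ``rare`` or ``intermediate``.

    Optimal: the designated family maximum (single-member families such as
    Met/Trp are always optimal).  Rare: synonym-relative frequency ≤ 0.10,
    boundary inclusive.  Optimal takes precedence over rare.  Members of a
    family never observed in the reference set are ``intermediate`` (their
    frequency is undefined, reported as 0).
    """
    triplet = triplet.upper()
    if triplet not in ALL_CODONS:
        raise PlastidkitError(f"invalid triplet {triplet!r}")
    aa = table.family_of(triplet)
    if len(table.family_codons(aa)) == 1:
        return "optimal"
    if aa in table.unobserved_families:
        return "intermediate"
    if triplet == table.optimal_codon(aa):
        return "optimal"
    if table.freq_among_synonyms[triplet] <= RARE_THRESHOLD:
        return "rare"
    return "intermediate"


def gene_usage_frequencies(
    cds: CdsRecord, genetic_code_id: int = DEFAULT_GENETIC_CODE
) -> dict[str, float]:
    """The gene's own synonym-relative codon frequencies (all 64 triplets)."""
    return dict(
        build_usage_table(
            [cds], genetic_code_id=genetic_code_id, include_stops=True
        ).freq_among_synonyms
    )


def mean_freq_diff(
    cds: CdsRecord, table: CodonUsageTable, variant: str = "position"
) -> float:
    """Mean absolute difference between gene and reference codon frequencies.

    All frequencies are synonym-relative.  Returned as a percentage.

    Variants:

    ``position``
        mean over codon positions of ``|f_gene(c) - f_ref(c)|`` where ``c``
        is the codon at that position (equivalently, occurrence-weighted mean
        over the triplets present in the gene).  Default.
    ``triplet_uniform``
        unweighted mean over all 64 triplets.
    ``gene_present``
        unweighted mean over the distinct triplets present in the gene.
    ``deficit``
        mean over codon positions of ``f_ref(best) - f_ref(c)`` where
        ``best`` is the family's most-used codon in the reference: how far
        short of the preferred synonym each used codon falls.  Zero iff the
        gene is fully optimal; never increased by optimal recoding.
    """
    if variant not in MEAN_FREQ_DIFF_VARIANTS:
        raise PlastidkitError(
            f"unknown mean_freq_diff variant {variant!r}; "
            f"choose one of {MEAN_FREQ_DIFF_VARIANTS}"
        )
    f_ref = table.freq_among_synonyms
    if variant == "deficit":
        total = sum(
            f_ref[table.optimal_codon(table.family_of(c))] - f_ref[c]
            for c in cds.codons
        )
        return 100.0 * total / cds.n_codons
    f_gene = gene_usage_frequencies(cds, table.genetic_code_id)
    if variant == "position":
        total = sum(abs(f_gene[c] - f_ref[c]) for c in cds.codons)
        return 100.0 * total / cds.n_codons
    if variant == "triplet_uniform":
        return 100.0 * sum(abs(f_gene[c] - f_ref[c]) for c in ALL_CODONS) / 64
    present = sorted(set(cds.codons))
    return 100.0 * sum(abs(f_gene[c] - f_ref[c]) for c in present) / len(present)


@dataclasses.dataclass(frozen=True)
class DiagnosticsReport:
    """All per-gene codon statistics against a reference usage table."""

    gene_id: str
    n_codons: int
    gc3: float
    n_optimal: int
    n_rare: int
    frac_optimal: float
    frac_rare: float
    mean_freq_diff: float
    mean_freq_diff_variant: str
    per_codon_classes: tuple[str, ...]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["per_codon_classes"] = list(self.per_codon_classes)
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_text(self) -> str:
        return (
            f"gene          : {self.gene_id}\n"
            f"codons        : {self.n_codons}\n"
            f"GC3           : {100 * self.gc3:.2f}%\n"
            f"optimal       : {self.n_optimal} ({100 * self.frac_optimal:.2f}%)\n"
            f"rare          : {self.n_rare} ({100 * self.frac_rare:.2f}%)\n"
            f"mean codon frequency difference "
            f"({self.mean_freq_diff_variant}): {self.mean_freq_diff:.2f}%\n"
        )


def diagnose(
    cds: CdsRecord,
    table: CodonUsageTable,
    variant: str = "position",
) -> DiagnosticsReport:
    """Compute the full diagnostics report for one gene against a table."""
    classes = tuple(classify_codon(c, table) for c in cds.codons)
    n_opt = classes.count("optimal")
    n_rare = classes.count("rare")
    n = cds.n_codons
    return DiagnosticsReport(
        gene_id=cds.id,
        n_codons=n,
        gc3=gc3(cds),
        n_optimal=n_opt,
        n_rare=n_rare,
        frac_optimal=n_opt / n,
        frac_rare=n_rare / n,
        mean_freq_diff=mean_freq_diff(cds, table, variant),
        mean_freq_diff_variant=variant,
        per_codon_classes=classes,
    )


@dataclasses.dataclass(frozen=True)
class ChangeSummary:
    """Synonymous-change accounting between two recodings of one protein."""

    n_changed: int
    n_total: int
    per_segment: tuple[int, ...]
    segment_size: int
    changed_positions: tuple[int, ...]  # 1-based codon indices

    def to_dict(self) -> dict:
        return {
            "n_changed": self.n_changed,
            "n_total": self.n_total,
            "per_segment": list(self.per_segment),
            "segment_size": self.segment_size,
            "changed_positions": list(self.changed_positions),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_text(self) -> str:
        seg = ", ".join(str(s) for s in self.per_segment)
        return (
            f"codons changed: {self.n_changed} / {self.n_total}\n"
            f"per {self.segment_size}-codon segment: [{seg}]\n"
        )


def compare_synonymous(
    a: CdsRecord,
    b: CdsRecord,
    segment_size: int = 80,
    genetic_code_id: int = DEFAULT_GENETIC_CODE,
) -> ChangeSummary:
    """Count codon positions at which two synonymous recodings differ.

    Segments are consecutive windows of ``segment_size`` codons, 1-based:
    [1..80], [81..160], ... (the last window may be short).  Raises
    :class:`NonSynonymousError` (with the offending 1-based positions) if the
    translations differ, and :class:`PlastidkitError` on unequal lengths.
    """
    if len(a.sequence) != len(b.sequence):
        raise PlastidkitError(
            f"sequences differ in length ({len(a.sequence)} vs {len(b.sequence)})"
        )
    if segment_size < 1:
        raise PlastidkitError("segment_size must be >= 1")
    ca, cb = a.codons, b.codons
    tmap = translation_map(genetic_code_id)
    bad = [i + 1 for i, (x, y) in enumerate(zip(ca, cb)) if tmap[x] != tmap[y]]
    if bad:
        raise NonSynonymousError(bad)
    changed = tuple(i + 1 for i, (x, y) in enumerate(zip(ca, cb)) if x != y)
    n = len(ca)
    n_segments = (n + segment_size - 1) // segment_size
    per_segment = [0] * n_segments
    for pos in changed:
        per_segment[(pos - 1) // segment_size] += 1
    return ChangeSummary(
        n_changed=len(changed),
        n_total=n,
        per_segment=tuple(per_segment),
        segment_size=segment_size,
        changed_positions=changed,
    )
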