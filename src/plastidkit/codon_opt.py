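"""Synonymous recoding of a CDS toward a reference codon-usage table.

Three strategies:

``max``
    every codon is replaced by its family's most frequent triplet in the
    reference table (lexicographic tie-break).  The output is 100 %
    "optimal" by construction — note that real synthesized reporters are
    often not (deliberate deviations for motif removal, secondary structure,
    vendor heuristics), so ``max`` is a ceiling, not a reconstruction.
``match``
    each codon is drawn from its synonym family with probabilities equal to
    the reference frequencies; reproducible for a fixed seed (NumPy
    ``default_rng``, PCG64).
``threshold``
    codons whose reference frequency is at or below ``rare_ceiling`` are
    promoted to the family optimum; all others are kept.

All strategies preserve the translation exactly.  Single-codon families
(Met, Trp under code 11) are never changed.  Optional forbidden motifs are
removed by a greedy synonymous re-choice pass; occurrences that cannot be
removed synonymously are reported, never silently ignored.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .codon_stats import (
    ChangeSummary,
    CdsRecord,
    CodonUsageTable,
    DiagnosticsReport,
    STOP_SYMBOL,
    compare_synonymous,
    diagnose,
    translation_map,
)
from .errors import PlastidkitError

STRATEGIES = ("max", "match", "threshold")


@dataclasses.dataclass(frozen=True)
class OptimizationSpec:
    strategy: str = "max"
    rare_ceiling: float = 0.10
    rng_seed: int | None = None
    forbidden_motifs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise PlastidkitError(
                f"unknown strategy {self.strategy!r}; choose one of {STRATEGIES}"
            )
        if not 0.0 <= self.rare_ceiling <= 1.0:
            raise PlastidkitError("rare_ceiling must be in [0, 1]")
        if self.strategy == "match" and self.rng_seed is None:
            raise PlastidkitError("the match strategy requires rng_seed")
        object.__setattr__(
            self,
            "forbidden_motifs",
            tuple(m.upper() for m in self.forbidden_motifs),
        )


@dataclasses.dataclass(frozen=True)
class OptimizationResult:
    cds: CdsRecord
    changes: ChangeSummary
    diagnostics_before: DiagnosticsReport
    diagnostics_after: DiagnosticsReport
    unavoidable_motifs: tuple[tuple[str, int], ...]  # (motif, 0-based nt offset)

    def to_json(self, spec: OptimizationSpec | None = None, **kw) -> str:
        d = {
            "gene_id": self.cds.id,
            "sequence": self.cds.sequence,
            "changes": self.changes.to_dict(),
            "diagnostics_before": self.diagnostics_before.to_dict(),
            "diagnostics_after": self.diagnostics_after.to_dict(),
            "unavoidable_motifs": [list(m) for m in self.unavoidable_motifs],
        }
        if spec is not None:
            d["spec"] = dataclasses.asdict(spec)
        return json.dumps(d, **kw)


def _choose_codon(
    codon: str,
    table: CodonUsageTable,
    spec: OptimizationSpec,
    rng: np.random.Generator | None,
) -> str:
    aa = table.family_of(codon)
    members = table.family_codons(aa)
    if len(members) == 1:
        return codon
    if spec.strategy == "max":
        return table.optimal_codon(aa)
    if spec.strategy == "threshold":
        if table.freq_among_synonyms[codon] <= spec.rare_ceiling:
            return table.optimal_codon(aa)
        return codon
    # match: sample proportional to reference frequencies; keep the original
    # codon if the family was never observed (no distribution to match).
    probs = np.array([table.freq_among_synonyms[c] for c in members], dtype=float)
    if probs.sum() == 0:
        return codon
    return members[rng.choice(len(members), p=probs / probs.sum())]


def _fix_motifs(
    codons: list[str],
    table: CodonUsageTable,
    motifs: tuple[str, ...],
) -> tuple[list[str], list[tuple[str, int]]]:
    """Greedy synonymous re-choice to remove forbidden motifs.

    For each motif occurrence, try every overlapping codon position and every
    alternative synonym (in decreasing reference frequency) until the local
    occurrence disappears; record occurrences no synonymous change can remove.
    """
    unavoidable: list[tuple[str, int]] = []
    for motif in motifs:
        guard = 0
        while guard < 10 * len(codons):
            guard += 1
            seq = "".join(codons)
            hit = seq.find(motif)
            if hit == -1:
                break
            first = hit // 3
            last = (hit + len(motif) - 1) // 3
            fixed = False
            for pos in range(first, last + 1):
                aa = table.family_of(codons[pos])
                alts = sorted(
                    (c for c in table.family_codons(aa) if c != codons[pos]),
                    key=lambda c: -table.freq_among_synonyms[c],
                )
                for alt in alts:
                    trial = codons.copy()
                    trial[pos] = alt
                    window = "".join(trial)[max(0, hit - len(motif)) : hit + 2 * len(motif)]
                    if motif not in window:
                        codons = trial
                        fixed = True
                        break
                if fixed:
                    break
            if not fixed:
                unavoidable.append((motif, hit))
                # mask this occurrence from further scanning by moving on:
                # re-find from the next offset
                nxt = seq.find(motif, hit + 1)
                if nxt == -1:
                    break
                hit = nxt
                break
    # final scan for anything still present and not yet reported
    seq = "".join(codons)
    for motif in motifs:
        start = 0
        while True:
            hit = seq.find(motif, start)
            if hit == -1:
                break
            if (motif, hit) not in unavoidable:
                unavoidable.append((motif, hit))
            start = hit + 1
    return codons, unavoidable


def optimize(
    cds: CdsRecord,
    table: CodonUsageTable,
    spec: OptimizationSpec,
    mean_freq_diff_variant: str = "position",
) -> OptimizationResult:
    """Recode ``cds`` toward ``table`` under ``spec``.

    The output translates identically to the input.  An internal stop codon
    in the input is rejected.  Under ``max`` the stop codon is recoded to the
    family-optimal stop; under ``threshold`` it is kept unless rare.
    """
    tmap = translation_map(table.genetic_code_id)
    aas = [tmap[c] for c in cds.codons]
    if STOP_SYMBOL in aas[:-1]:
        where = [i + 1 for i, a in enumerate(aas[:-1]) if a == STOP_SYMBOL]
        raise PlastidkitError(
            f"internal stop codon(s) at codon position(s) {where}"
        )
    rng = (
        np.random.default_rng(spec.rng_seed)
        if spec.rng_seed is not None
        else None
    )
    out = [_choose_codon(c, table, spec, rng) for c in cds.codons]
    unavoidable: list[tuple[str, int]] = []
    if spec.forbidden_motifs:
        out, unavoidable = _fix_motifs(out, table, spec.forbidden_motifs)
    recoded = CdsRecord(id=f"{cds.id}|{spec.strategy}", sequence="".join(out))
    return OptimizationResult(
        cds=recoded,
        changes=compare_synonymous(
            cds, recoded, genetic_code_id=table.genetic_code_id
        ),
        diagnostics_before=diagnose(cds, table, mean_freq_diff_variant),
        diagnostics_after=diagnose(recoded, table, mean_freq_diff_variant),
        unavoidable_motifs=tuple(unavoidable),
    )
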