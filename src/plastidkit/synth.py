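"""Synthetic data generators with recorded ground truth.

Every generator in this module is seeded through NumPy's ``default_rng``
(PCG64) and is bit-reproducible for a fixed seed.  They provide a
download-free test surface for the rest of the package:

* CDS sets drawn from a known synonymous-frequency profile (optionally with
  a target GC3, emulating an AT-rich plastome coding complement);
* a plastome-like GenBank record whose CDS features include minus-strand
  and spliced (join) genes plus an inverted-repeat duplicate pair;
* synonymous sequence pairs with an exactly known number and placement of
  codon changes;
* genes built with an exactly known optimal/rare/intermediate codon
  composition against a given usage table;
* two-channel plastid scenes: disc-shaped particles with Gaussian edge
  falloff, a configurable reporter/autofluorescence ratio per particle, and
  optional touching pairs for watershed tests;
* serial-dilution gel band densities on a known line with additive Gaussian
  noise.

Synthetic scenes are deliberately simple optics: no PSF, no depth
attenuation, no chromatic offset.  What they establish is that the
measurement code recovers known ground truth, not that it is robust to
every artifact of real confocal data.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .codon_stats import (
    ALL_CODONS,
    CdsRecord,
    CodonUsageTable,
    DEFAULT_GENETIC_CODE,
    STOP_SYMBOL,
    synonym_families,
)
from .errors import PlastidkitError
from .fluor_quant import TwoChannelImage


# ---------------------------------------------------------------------------
# codon-usage profiles and CDS sets
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class UsageProfileSpec:
    """Per-family synonymous codon frequency vectors (ground truth).

    ``families`` maps amino acid (or ``*``) to a codon→frequency mapping
    summing to 1 within each family.  ``aa_weights`` gives the amino-acid
    composition used when drawing sequences (uniform over the 20 amino acids
    by default; stops are placed only at the terminus).
    """

    families: Mapping[str, Mapping[str, float]]
    genetic_code_id: int = DEFAULT_GENETIC_CODE
    aa_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        fams = synonym_families(self.genetic_code_id)
        for aa, vec in self.families.items():
            if set(vec) != set(fams[aa]):
                raise PlastidkitError(f"profile for {aa!r} must cover exactly its codons")
            if abs(sum(vec.values()) - 1.0) > 1e-9:
                raise PlastidkitError(f"profile for {aa!r} does not sum to 1")

    @classmethod
    def uniform(cls, genetic_code_id: int = DEFAULT_GENETIC_CODE) -> "UsageProfileSpec":
        fams = synonym_families(genetic_code_id)
        return cls(
            families={
                aa: {c: 1.0 / len(codons) for c in codons}
                for aa, codons in fams.items()
            },
            genetic_code_id=genetic_code_id,
        )

    @classmethod
    def from_gc3(
        cls, target_gc3: float, genetic_code_id: int = DEFAULT_GENETIC_CODE
    ) -> "UsageProfileSpec":
        """A profile whose expected GC3 over random genes equals the target.

        Single-codon families (Met ATG, Trp TGG under code 11) force a
        G-ending codon; with uniform amino-acid weights they contribute 2/20
        of positions, so the G/C-ending mass of the free families is
        compensated to keep the overall expectation on target.
        """
        if not 0.0 <= target_gc3 <= 1.0:
            raise PlastidkitError("target_gc3 must be in [0, 1]")
        fams = synonym_families(genetic_code_id)
        aas = sorted(a for a in fams if a != STOP_SYMBOL)
        forced = [a for a in aas if len(fams[a]) == 1]
        w_forced = sum(1.0 for a in forced if fams[a][0][2] in "GC") / len(aas)
        w_free = 1.0 - len(forced) / len(aas)
        p_free = (target_gc3 - w_forced) / w_free
        p_free = min(max(p_free, 0.0), 1.0)
        families: dict[str, dict[str, float]] = {}
        for aa, codons in fams.items():
            gc_group = [c for c in codons if c[2] in "GC"]
            at_group = [c for c in codons if c[2] not in "GC"]
            if not gc_group or not at_group:
                families[aa] = {c: 1.0 / len(codons) for c in codons}
                continue
            vec = {c: p_free / len(gc_group) for c in gc_group}
            vec.update({c: (1.0 - p_free) / len(at_group) for c in at_group})
            families[aa] = vec
        return cls(families=families, genetic_code_id=genetic_code_id)

    def to_usage_table(self, scale: int = 10_000) -> CodonUsageTable:
        """Render the profile as a usage table (counts = scaled frequencies)."""
        counts = {c: 0 for c in ALL_CODONS}
        for vec in self.families.values():
            for codon, f in vec.items():
                counts[codon] = int(round(f * scale))
        return CodonUsageTable.from_counts(
            counts, genetic_code_id=self.genetic_code_id, n_cds=0, include_stops=True
        )


def _draw_codon(rng: np.random.Generator, vec: Mapping[str, float]) -> str:
    codons = sorted(vec)
    probs = np.array([vec[c] for c in codons], dtype=float)
    return codons[rng.choice(len(codons), p=probs / probs.sum())]


def gen_cds_set(
    n_cds: int,
    mean_length_codons: int,
    profile: UsageProfileSpec,
    rng_seed: int,
) -> tuple[list[CdsRecord], UsageProfileSpec]:
    """Draw a CDS set from a known profile; returns (records, true profile).

    Each gene starts with ATG, ends with exactly one stop drawn from the
    stop-family profile, and has Poisson-distributed interior length around
    ``mean_length_codons``.  Interior amino acids are drawn from
    ``profile.aa_weights`` (uniform default), codons from the family vectors.
    """
    if n_cds < 1 or mean_length_codons < 4:
        raise PlastidkitError("need n_cds >= 1 and mean_length_codons >= 4")
    rng = np.random.default_rng(rng_seed)
    fams = synonym_families(profile.genetic_code_id)
    aas = sorted(a for a in fams if a != STOP_SYMBOL)
    if profile.aa_weights is None:
        weights = np.full(len(aas), 1.0 / len(aas))
    else:
        weights = np.array([profile.aa_weights.get(a, 0.0) for a in aas])
        weights = weights / weights.sum()
    records = []
    for i in range(n_cds):
        n_interior = max(2, int(rng.poisson(mean_length_codons - 2)))
        codons = ["ATG"]
        for _ in range(n_interior):
            aa = aas[rng.choice(len(aas), p=weights)]
            codons.append(_draw_codon(rng, profile.families[aa]))
        codons.append(_draw_codon(rng, profile.families[STOP_SYMBOL]))
        records.append(CdsRecord(id=f"syn_{i:03d}", sequence="".join(codons)))
    return records, profile


def gen_synonymous_pair(
    n_codons: int,
    changes_per_segment: Sequence[int],
    segment_size: int,
    profile: UsageProfileSpec,
    rng_seed: int,
) -> tuple[CdsRecord, CdsRecord, tuple[int, ...]]:
    """A synthetic gene and a synonymous recoding with exact known changes.

    ``changes_per_segment[k]`` positions are recoded within codon window
    ``[k·segment_size + 1 … (k+1)·segment_size]`` (1-based).  Positions
    chosen for change always carry a multi-codon family, so a different
    synonym exists.  Returns (original, recoded, changed positions).
    """
    rng = np.random.default_rng(rng_seed)
    fams = synonym_families(profile.genetic_code_id)
    multi = sorted(a for a in fams if a != STOP_SYMBOL and len(fams[a]) > 1)
    single = sorted(a for a in fams if a != STOP_SYMBOL and len(fams[a]) == 1)
    n_segments = (n_codons + segment_size - 1) // segment_size
    if len(changes_per_segment) > n_segments:
        raise PlastidkitError("more change segments than sequence segments")
    change_set: set[int] = set()
    for k, n_changes in enumerate(changes_per_segment):
        lo = k * segment_size + 1
        hi = min((k + 1) * segment_size, n_codons)
        # keep codon 1 (forced ATG start) and the terminal stop recodable:
        # the stop family has 3 members under code 11, the Met start does not.
        avail = [p for p in range(lo, hi + 1) if p != 1]
        if n_changes > len(avail):
            raise PlastidkitError(f"segment {k} cannot host {n_changes} changes")
        change_set.update(
            int(p) for p in rng.choice(avail, size=n_changes, replace=False)
        )
    codons_a: list[str] = []
    codons_b: list[str] = []
    stop_vec = profile.families[STOP_SYMBOL]
    for pos in range(1, n_codons + 1):
        if pos == 1:
            codons_a.append("ATG")
            codons_b.append("ATG")
            continue
        if pos == n_codons:
            aa = STOP_SYMBOL
            vec = stop_vec
        elif pos in change_set:
            aa = multi[rng.integers(len(multi))]
            vec = profile.families[aa]
        else:
            aa = (multi + single)[rng.integers(len(multi) + len(single))]
            vec = profile.families[aa]
        codon = _draw_codon(rng, vec)
        codons_a.append(codon)
        if pos in change_set:
            alts = sorted(c for c in fams[aa] if c != codon)
            codons_b.append(alts[rng.integers(len(alts))])
        else:
            codons_b.append(codon)
    return (
        CdsRecord(id="pair_a", sequence="".join(codons_a)),
        CdsRecord(id="pair_b", sequence="".join(codons_b)),
        tuple(sorted(change_set)),
    )


def gen_gc3_cds(n_codons: int, n_gc3: int, rng_seed: int) -> CdsRecord:
    """A synthetic CDS with exactly ``n_gc3`` of ``n_codons`` G/C third bases.

    Built from Lys (AAA/AAG) and Asn (AAT/AAC) codons whose third base alone
    decides GC3, with an ATG start (G-ending, counted toward ``n_gc3``) and a
    terminal stop chosen to match its slot's assigned third-base class.
    """
    if not 1 <= n_gc3 <= n_codons:
        raise PlastidkitError("need 1 <= n_gc3 <= n_codons (ATG start ends in G)")
    rng = np.random.default_rng(rng_seed)
    gc_slots = np.zeros(n_codons, dtype=bool)
    gc_slots[0] = True  # ATG
    extra = rng.choice(np.arange(1, n_codons), size=n_gc3 - 1, replace=False)
    gc_slots[extra] = True
    codons = ["ATG"]
    for pos in range(1, n_codons - 1):
        if gc_slots[pos]:
            codons.append("AAG" if rng.random() < 0.5 else "AAC")
        else:
            codons.append("AAA" if rng.random() < 0.5 else "AAT")
    codons.append("TAG" if gc_slots[n_codons - 1] else "TAA")
    return CdsRecord(id=f"gc3_{n_gc3}_of_{n_codons}", sequence="".join(codons))


def gen_classified_cds(
    n_optimal: int,
    n_rare: int,
    n_intermediate: int,
    table: CodonUsageTable,
    rng_seed: int,
) -> CdsRecord:
    """A synthetic gene with an exact optimal/rare/intermediate composition.

    Codons are drawn from the pools the table itself classifies as optimal,
    rare or intermediate (stop family excluded except for the terminus).
    The gene starts ATG — consuming one optimal slot, since single-codon
    families are always optimal — and ends with the table's optimal stop if
    an optimal slot remains for it, otherwise a rare or intermediate stop.
    Raises if the table offers no codon of a requested class.
    """
    if n_optimal < 1:
        raise PlastidkitError("need n_optimal >= 1 (the ATG start is optimal)")
    rng = np.random.default_rng(rng_seed)
    pools: dict[str, list[str]] = {"optimal": [], "rare": [], "intermediate": []}
    for codon in ALL_CODONS:
        if table.family_of(codon) == STOP_SYMBOL:
            continue
        if codon == "ATG":
            continue
        pools[table.classify(codon)].append(codon)
    stop_by_class: dict[str, list[str]] = {"optimal": [], "rare": [], "intermediate": []}
    for codon in table.family_codons(STOP_SYMBOL):
        stop_by_class[table.classify(codon)].append(codon)

    need = {"optimal": n_optimal - 1, "rare": n_rare, "intermediate": n_intermediate}
    # assign the terminal stop to a class that still needs a slot and offers one
    stop_class = next(
        (
            cls
            for cls in ("optimal", "rare", "intermediate")
            if need[cls] > 0 and stop_by_class[cls]
        ),
        None,
    )
    if stop_class is None:
        raise PlastidkitError("no stop codon available for the requested composition")
    need[stop_class] -= 1
    for cls, n in need.items():
        if n > 0 and not pools[cls]:
            raise PlastidkitError(f"table offers no {cls} sense codons")
    body = []
    for cls, n in need.items():
        pool = pools[cls]
        body.extend(pool[i] for i in rng.integers(len(pool), size=n))
    order = rng.permutation(len(body))
    codons = ["ATG"] + [body[i] for i in order] + [sorted(stop_by_class[stop_class])[0]]
    return CdsRecord(
        id=f"classified_{n_optimal}o_{n_rare}r_{n_intermediate}i",
        sequence="".join(codons),
    )


# ---------------------------------------------------------------------------
# plastome-like GenBank records
# ---------------------------------------------------------------------------

def gen_plastome_record(
    n_cds: int = 94,
    mean_length_codons: int = 250,
    target_gc3: float = 0.121,
    rng_seed: int = 0,
    spacer_length: int = 60,
    frac_minus_strand: float = 0.4,
    frac_spliced: float = 0.1,
    n_ir_duplicates: int = 2,
) -> tuple[SeqRecord, list[CdsRecord]]:
    """A synthetic plastome-like GenBank record with annotated CDS features.

    Genes are drawn from a GC3-targeted profile; a fraction are placed on
    the minus strand (``complement(...)`` locations) and a fraction split in
    two exons (``join(...)`` locations).  The last ``n_ir_duplicates`` genes
    are duplicated verbatim under the same gene name, emulating the
    inverted-repeat double annotation.  Returns the record plus the true
    CDS set (duplicates listed once).
    """
    rng = np.random.default_rng(rng_seed)
    profile = UsageProfileSpec.from_gc3(target_gc3)
    genes, _ = gen_cds_set(n_cds, mean_length_codons, profile, rng_seed=int(rng.integers(2**31)))
    spacer_bases = np.array(list("AT"))
    parts: list[str] = []
    features: list[SeqFeature] = []
    offset = 0

    def add_spacer() -> None:
        nonlocal offset
        spacer = "".join(rng.choice(spacer_bases, size=spacer_length))
        parts.append(spacer)
        offset += len(spacer)

    placements = list(genes) + genes[len(genes) - n_ir_duplicates :]
    for gene in placements:
        add_spacer()
        minus = rng.random() < frac_minus_strand
        spliced = rng.random() < frac_spliced and gene.n_codons >= 20
        seq = gene.sequence if not minus else str(Seq(gene.sequence).reverse_complement())
        if spliced:
            cut = 3 * int(rng.integers(5, gene.n_codons - 5))
            intron = "".join(rng.choice(spacer_bases, size=40))
            exon1, exon2 = seq[:cut], seq[cut:]
            parts.append(exon1)
            parts.append(intron)
            parts.append(exon2)
            loc1 = SimpleLocation(offset, offset + len(exon1), strand=-1 if minus else 1)
            start2 = offset + len(exon1) + len(intron)
            loc2 = SimpleLocation(start2, start2 + len(exon2), strand=-1 if minus else 1)
            # on the minus strand the downstream exon comes first in the join
            ordered = [loc2, loc1] if minus else [loc1, loc2]
            location = CompoundLocation(ordered)
            offset = start2 + len(exon2)
        else:
            parts.append(seq)
            location = SimpleLocation(offset, offset + len(seq), strand=-1 if minus else 1)
            offset += len(seq)
        features.append(
            SeqFeature(location, type="CDS", qualifiers={"gene": [gene.id]})
        )
    add_spacer()
    record = SeqRecord(
        Seq("".join(parts)),
        id="SYNPLASTOME",
        name="SYNPLASTOME",
        description="synthetic plastome-like record with annotated CDS",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    record.features = features
    return record, genes


# ---------------------------------------------------------------------------
# two-channel plastid scenes
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ImageSceneSpec:
    """Parameters of a synthetic two-channel plastid scene."""

    n_particles: int = 8
    radius_range: tuple[float, float] = (3.0, 4.5)
    cfp_auto_ratio: float = 4.0
    auto_amplitude: float = 200.0
    background_cfp: float = 5.0
    background_auto: float = 10.0
    noise_sd: float = 0.0
    overlap_fraction: float = 0.0
    edge_sigma: float = 1.0
    shape: tuple[int, int] = (160, 160)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cfp_auto_ratio <= 0:
            raise PlastidkitError("cfp_auto_ratio must be positive")
        if self.noise_sd < 0:
            raise PlastidkitError("noise_sd must be >= 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise PlastidkitError("overlap_fraction must be in [0, 1]")


@dataclasses.dataclass(frozen=True)
class SceneTruth:
    labels: np.ndarray
    ratios: tuple[float, ...]  # per-particle CFP/auto ratio before noise
    centers: tuple[tuple[float, float], ...]
    radii: tuple[float, ...]


def gen_plastid_scene(spec: ImageSceneSpec) -> tuple[TwoChannelImage, SceneTruth]:
    """Render a two-channel scene of disc particles with known ratios.

    Each particle is a disc of constant autofluorescence amplitude with a
    Gaussian edge falloff; the reporter channel is ``ratio ×`` the particle's
    autofluorescence signal before backgrounds and noise are added, so the
    per-particle foreground ratio is exact ground truth.  When
    ``overlap_fraction > 0`` the required number of particles are placed as
    touching pairs (center distance 1.5 × radius) for watershed testing.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.shape
    r_lo, r_hi = spec.radius_range
    margin = r_hi + 4 * spec.edge_sigma

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    n_paired = int(round(spec.overlap_fraction * spec.n_particles))
    if spec.overlap_fraction > 0 and n_paired < 2:
        n_paired = 2
    n_pairs = n_paired // 2

    def far_enough(y: float, x: float, r: float, min_gap: float) -> bool:
        return all(
            np.hypot(y - cy, x - cx) >= (r + cr + min_gap)
            for (cy, cx), cr in zip(centers, radii)
        )

    def place(r: float, min_gap: float, extra_margin: float = 0.0) -> tuple[float, float]:
        m = margin + extra_margin
        for _ in range(3000):
            y = rng.uniform(m, h - m)
            x = rng.uniform(m, w - m)
            if far_enough(y, x, r, min_gap):
                return y, x
        raise PlastidkitError("could not place particles; scene too crowded")

    for _ in range(n_pairs):
        r = rng.uniform(r_lo, r_hi)
        y, x = place(r + 1.5 * r, 4.0, extra_margin=1.5 * r)
        theta = rng.uniform(0, 2 * np.pi)
        centers.append((y, x))
        radii.append(r)
        centers.append((y + 1.5 * r * np.sin(theta), x + 1.5 * r * np.cos(theta)))
        radii.append(r)
    while len(centers) < spec.n_particles:
        r = rng.uniform(r_lo, r_hi)
        y, x = place(r, 4.0)
        centers.append((y, x))
        radii.append(r)

    yy, xx = np.mgrid[0:h, 0:w]
    auto_fg = np.zeros((h, w))
    labels = np.zeros((h, w), dtype=np.int32)
    best_d = np.full((h, w), np.inf)
    # truth extent = half-maximum contour of the edge falloff
    r_half = spec.edge_sigma * np.sqrt(2.0 * np.log(2.0))
    for k, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        d = np.hypot(yy - cy, xx - cx)
        profile = np.where(
            d <= r, 1.0, np.exp(-((d - r) ** 2) / (2 * spec.edge_sigma**2))
        )
        auto_fg = np.maximum(auto_fg, spec.auto_amplitude * profile)
        inside = d <= r + r_half
        claim = inside & (d < best_d)
        labels[claim] = k
        best_d[claim] = d[claim]

    cfp = spec.cfp_auto_ratio * auto_fg + spec.background_cfp
    auto = auto_fg + spec.background_auto
    if spec.noise_sd > 0:
        cfp = cfp + rng.normal(0.0, spec.noise_sd, size=cfp.shape)
        auto = auto + rng.normal(0.0, spec.noise_sd, size=auto.shape)
    image = TwoChannelImage(cfp=np.clip(cfp, 0, None), auto=np.clip(auto, 0, None))
    truth = SceneTruth(
        labels=labels,
        ratios=tuple(spec.cfp_auto_ratio for _ in centers),
        centers=tuple((float(y), float(x)) for y, x in centers),
        radii=tuple(float(r) for r in radii),
    )
    return image, truth


# ---------------------------------------------------------------------------
# gel band density series
# ---------------------------------------------------------------------------

def gen_gel_series(
    slope: float,
    intercept: float,
    amounts_ng: Sequence[float],
    noise_sd: float,
    rng_seed: int,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Band densities on a known line with additive Gaussian noise.

    Returns a table with one row per amount and replicate columns
    ``density_1 … density_n``, plus the ground-truth parameters.
    """
    if noise_sd < 0:
        raise PlastidkitError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng_seed)
    amounts = np.asarray(amounts_ng, dtype=float)
    clean = slope * amounts + intercept
    reps = clean[:, None] + rng.normal(0.0, noise_sd, size=(amounts.size, n_replicates))
    table = pd.DataFrame(
        {"amount_ng": amounts}
        | {f"density_{j + 1}": reps[:, j] for j in range(n_replicates)}
    )
    truth = {"slope": slope, "intercept": intercept, "noise_sd": noise_sd}
    return table, truth


def serial_dilution(top_ng: float = 1000.0, n_points: int = 10) -> list[float]:
    """Two-fold serial dilution amounts starting from ``top_ng``."""
    return [top_ng / 2**k for k in range(n_points)]
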