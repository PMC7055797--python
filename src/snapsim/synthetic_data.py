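"""Synthetic coverage/pileup data emulating duplication signals.

Generates every input the scanner needs without any sequencing data:
random reference sequences (optionally with an embedded CDS), per-base
depth tracks with duplicated blocks at elevated copy number, and pileup
tables with divergent sites at a chosen allele fraction, together with
truth files for benchmarking.

Depth is drawn per base from a negative binomial with mean
``mean_depth * copy_number`` -- real short-read coverage is overdispersed
relative to Poisson, and the dispersion parameter interpolates from the
Poisson limit (0) to strongly clumped coverage.  Bases are drawn
independently: there is no read-length autocorrelation, which is
sufficient for windowed statistics but understates the variance of window
means relative to real libraries (a documented limitation).

The bundled :func:`diverging_dup_fixture` mirrors the one fully worked natural
example the scanner is calibrated against: a 21 kb duplication at copy
number 2, a single 1-bp thymine insertion inside an annotated CDS within
the duplication, site depth ~155 and a true alternate fraction of 0.49.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .coverage_scan import CoverageTrack, GeneAnnotation, PILEUP_COLUMNS

__all__ = [
    "SyntheticSpec",
    "DivergingDupFixture",
    "make_reference",
    "copy_number_profile",
    "simulate_coverage",
    "simulate_pileup",
    "diverging_dup_fixture",
]

BASES = np.array(list("ACGT"))
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic contig's coverage and pileup signal.

    duplications: (start, end, copy_number) triples, 0-based half-open,
        non-overlapping, within the contig.
    divergent_sites: (position, alternate allele, true fraction) triples;
        alleles use the scanner's notation (base substitution, ``+SEQ``
        insertion, ``-SEQ`` deletion).
    """

    length: int
    mean_depth: float = 150.0
    dispersion: float = 0.05
    duplications: List[Tuple[int, int, int]] = field(default_factory=list)
    divergent_sites: List[Tuple[int, str, float]] = field(default_factory=list)
    seed: int = 0
    contig: str = "synthetic_1"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("contig length must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        last_end = 0
        for start, end, copy in sorted(self.duplications):
            if not (0 <= start < end <= self.length):
                raise ValueError(f"duplication ({start}, {end}) outside contig")
            if start < last_end:
                raise ValueError("duplications must not overlap")
            if copy < 1:
                raise ValueError("copy number must be >= 1")
            last_end = end
        for pos, allele, frac in self.divergent_sites:
            if not 0 <= pos < self.length:
                raise ValueError(f"divergent site {pos} outside contig")
            if not allele:
                raise ValueError("divergent allele must be non-empty")
            if not 0 < frac < 1:
                raise ValueError("true fraction must lie in (0, 1)")


def make_reference(
    length: int,
    seed: int,
    cds: Optional[Tuple[int, int, str]] = None,
    contig: str = "synthetic_1",
) -> Tuple[str, Optional[GeneAnnotation]]:
    """Uniform-random nucleotide sequence, optionally with an embedded CDS.

    ``cds = (start, n_codons, strand)`` embeds an open reading frame of
    ``n_codons`` codons (ATG start, random internal codons free of stop
    codons, one stop codon) at the given position; the matching
    :class:`GeneAnnotation` is returned alongside.  Same seed, same bytes.
    """
    if length < 1000:
        raise ValueError("reference length must be at least 1000 bp")
    rng = np.random.default_rng([seed, 2])
    seq = rng.choice(BASES, size=length)

    annotation = None
    if cds is not None:
        start, n_codons, strand = cds
        if n_codons < 3:
            raise ValueError("CDS needs at least start, one internal and stop codon")
        cds_len = 3 * n_codons
        if not (0 <= start and start + cds_len <= length):
            raise ValueError("CDS does not fit inside the reference")
        codons = ["ATG"]
        while len(codons) < n_codons - 1:
            c = "".join(rng.choice(BASES, size=3))
            if c not in STOP_CODONS:
                codons.append(c)
        codons.append(sorted(STOP_CODONS)[rng.integers(len(STOP_CODONS))])
        orf = "".join(codons)
        if strand == "-":
            comp = str.maketrans("ACGT", "TGCA")
            orf = orf.translate(comp)[::-1]
        seq[start : start + cds_len] = list(orf)
        annotation = GeneAnnotation(
            gene_id="synthetic_gene_1",
            contig=contig,
            strand=strand,
            intervals=[(start, start + cds_len)],
        )
    return "".join(seq), annotation


def copy_number_profile(spec: SyntheticSpec) -> np.ndarray:
    """Per-base copy number (1 outside duplications)."""
    profile = np.ones(spec.length)
    for start, end, copy in spec.duplications:
        profile[start:end] = copy
    return profile


def _nb_depth(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Negative-binomial depth with var = mean + dispersion * mean^2.

    dispersion == 0 degenerates to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=mean.shape if mean.shape else None)


def simulate_coverage(
    spec: SyntheticSpec, rng: Optional[np.random.Generator] = None
) -> Tuple[CoverageTrack, pd.DataFrame]:
    """Draw a per-base depth track plus its truth table.

    Depth at each base is negative-binomial with mean
    ``mean_depth * copy_number``; the truth table lists the duplicated
    intervals (BED-like columns contig/start/end/copy).
    """
    if rng is None:
        rng = np.random.default_rng([spec.seed, 0])
    mean = spec.mean_depth * copy_number_profile(spec)
    depth = _nb_depth(rng, mean, spec.dispersion)
    truth = pd.DataFrame(
        [(spec.contig, s, e, c) for s, e, c in sorted(spec.duplications)],
        columns=["contig", "start", "end", "copy"],
    )
    return CoverageTrack(contig=spec.contig, depth=depth), truth


def simulate_pileup(
    spec: SyntheticSpec,
    track: Optional[CoverageTrack] = None,
    reference: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw allele counts at the divergent sites plus a truth table.

    Site depth is taken from the coverage track when one is supplied
    (keeping pileup and track consistent), otherwise drawn from the same
    negative-binomial model.  The alternate count is binomial with the
    site's true fraction; the remainder is reference.  Reference bases
    come from ``reference`` when given, else 'A'.
    """
    if rng is None:
        rng = np.random.default_rng([spec.seed, 1])
    profile = copy_number_profile(spec)
    rows = []
    truth_rows = []
    for pos, allele, frac in spec.divergent_sites:
        expected = spec.mean_depth * profile[pos]
        if track is not None:
            depth = int(track.depth[pos])
        else:
            depth = int(_nb_depth(rng, np.array(expected), spec.dispersion))
        alt = int(rng.binomial(depth, frac)) if depth > 0 else 0
        ref_base = reference[pos] if reference is not None else "A"
        rows.append((spec.contig, pos, ref_base, ref_base, depth - alt))
        rows.append((spec.contig, pos, ref_base, allele, alt))
        truth_rows.append((spec.contig, pos, allele, frac, expected, depth, alt))
    pileup = pd.DataFrame(rows, columns=PILEUP_COLUMNS)
    truth = pd.DataFrame(
        truth_rows,
        columns=["contig", "pos", "allele", "true_fraction", "expected_depth", "depth", "alt_count"],
    )
    return pileup, truth


@dataclass
class DivergingDupFixture:
    """Bundled synthetic worked example (one diverging 21 kb duplication)."""

    spec: SyntheticSpec
    reference: str
    annotation: GeneAnnotation
    track: CoverageTrack
    pileup: pd.DataFrame
    truth_duplications: pd.DataFrame
    truth_sites: pd.DataFrame
    site: int


# Geometry of the bundled worked example: 21 kb duplication at copy 2 in a
# 120 kb contig, background depth 77.5 so the duplicated divergent site
# sits at ~155x, and a 1-bp T insertion at true fraction 0.49 inside an
# annotated 401-codon CDS.
_FIXTURE_LENGTH = 120_000
_FIXTURE_DUP = (50_000, 71_000, 2)
_FIXTURE_CDS_START = 58_000
_FIXTURE_CDS_CODONS = 401
_FIXTURE_SITE = 58_600
_FIXTURE_MEAN_DEPTH = 77.5
_FIXTURE_FRACTION = 0.49
_FIXTURE_CONTIG = "synthetic_chromosome"


def diverging_dup_fixture(seed: int, out_dir: Optional[Path] = None) -> DivergingDupFixture:
    """Deterministic scanner fixture mirroring the worked natural example.

    Same seed, byte-identical outputs.  When ``out_dir`` is given the
    fixture is also written to disk as FASTA + GFF3 + bedGraph + pileup
    TSV + truth BED/TSV.
    """
    spec = SyntheticSpec(
        length=_FIXTURE_LENGTH,
        mean_depth=_FIXTURE_MEAN_DEPTH,
        dispersion=0.05,
        duplications=[_FIXTURE_DUP],
        divergent_sites=[(_FIXTURE_SITE, "+T", _FIXTURE_FRACTION)],
        seed=seed,
        contig=_FIXTURE_CONTIG,
    )
    reference, annotation = make_reference(
        spec.length,
        seed=seed,
        cds=(_FIXTURE_CDS_START, _FIXTURE_CDS_CODONS, "+"),
        contig=spec.contig,
    )
    track, truth_dups = simulate_coverage(spec)
    pileup, truth_sites = simulate_pileup(spec, track=track, reference=reference)
    fixture = DivergingDupFixture(
        spec=spec,
        reference=reference,
        annotation=annotation,
        track=track,
        pileup=pileup,
        truth_duplications=truth_dups,
        truth_sites=truth_sites,
        site=_FIXTURE_SITE,
    )
    if out_dir is not None:
        from . import io as snapio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        snapio.write_fasta(reference, spec.contig, out / "reference.fasta")
        snapio.write_gff([annotation], out / "annotation.gff3")
        snapio.write_coverage(track, out / "coverage.bedgraph")
        snapio.write_pileup(pileup, out / "pileup.tsv")
        truth_dups.to_csv(out / "truth_duplications.bed", sep="\t", index=False, header=False)
        truth_sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    return fixture
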