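"""Read-depth scanner for chromosomal duplications and diverging copies.

A tandem duplication doubles the number of reads mapping to the duplicated
segment, so it appears as a ~2x block in a per-base coverage track.  When
the two copies of a duplicated segment have started to diverge (e.g. an
inactivating frameshift in one copy), reads from both copies pile up on
the same reference position and the variant shows up at ~50% allele
fraction -- a heterozygous-like signal in a haploid genome.

The scanner formalizes this into a deterministic caller:

1. slide a window (default 1 kb, step 100 bp) along the depth track and
   record min/mean/max depth per window;
2. normalize window means by the genome-wide median window mean (a robust
   baseline that ignores duplicated blocks covering <50% of windows);
3. call maximal runs of windows at ratio >= ``min_ratio``, merge runs
   separated by small gaps, and drop short calls.  Call boundaries are
   placed at the centers of the outermost qualifying windows: a window
   first exceeds the ratio threshold when it half-overlaps a 2x block, so
   the window center -- not its edge -- tracks the true breakpoint (to
   within one step);
4. inside called duplications, report pileup sites whose strongest
   non-reference allele lies in a mid-range fraction band (default
   0.3-0.7) at adequate depth -- candidate diverging copies;
5. optionally classify the variant effect against a CDS annotation
   (frameshift / in-frame indel / missense / synonymous / nonsense /
   intergenic).

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "CoverageTrack",
    "DuplicationCall",
    "DivergenceCall",
    "GeneAnnotation",
    "AnnotationError",
    "sliding_window_stats",
    "normalize_coverage",
    "call_duplications",
    "call_divergent_sites",
    "classify_effect",
    "scan",
]

PILEUP_COLUMNS = ["contig", "pos", "ref", "allele", "count"]


@dataclass
class CoverageTrack:
    """Per-base read depth along one contig (0-based, half-open)."""

    contig: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise ValueError("depth must be a non-empty 1-D array")
        if np.any(self.depth < 0):
            raise ValueError("depth must be non-negative everywhere")

    def __len__(self) -> int:
        return int(self.depth.size)


@dataclass(frozen=True)
class DuplicationCall:
    """A detected duplicated interval."""

    contig: str
    start: int
    end: int
    mean_ratio: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("call end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class DivergenceCall:
    """A site inside a duplication where one copy has diverged."""

    contig: str
    pos: int
    ref: str
    alt: str
    depth: int
    fraction: float
    duplication: DuplicationCall
    effect: Optional[str] = None


class AnnotationError(ValueError):
    """A CDS annotation is malformed (e.g. length not a multiple of 3)."""


@dataclass
class GeneAnnotation:
    """CDS annotation of one gene: spliced intervals, strand and phase."""

    gene_id: str
    contig: str
    strand: str
    intervals: List[Tuple[int, int]]  # 0-based half-open, ascending
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        self.intervals = sorted((int(s), int(e)) for s, e in self.intervals)
        for s, e in self.intervals:
            if e <= s:
                raise AnnotationError(f"{self.gene_id}: empty CDS interval ({s}, {e})")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.intervals)

    def cds_offset(self, pos: int) -> int:
        """Offset of a genomic position within the spliced, stranded CDS."""
        if not self.contains(pos):
            raise ValueError(f"position {pos} not inside CDS of {self.gene_id}")
        fwd = 0
        for s, e in self.intervals:
            if pos < s:
                break
            if pos < e:
                fwd += pos - s
                break
            fwd += e - s
        if self.strand == "+":
            off = fwd - self.phase
        else:
            off = (self.cds_length - 1 - fwd) - self.phase
        if off < 0:
            raise AnnotationError(f"{self.gene_id}: position precedes reading frame start")
        return off

    def cds_sequence(self, reference: str) -> str:
        chunks = [reference[s:e] for s, e in self.intervals]
        seq = "".join(chunks)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq[self.phase :]


def sliding_window_stats(
    track: CoverageTrack, window: int = 1000, step: int = 100
) -> pd.DataFrame:
    """Min/mean/max depth over a sliding window.

    Returns one row per window start (0, step, 2*step, ...) with columns
    ``start, end, min, mean, max``; the trailing partial window is
    dropped.
    """
    n = len(track)
    if window > n:
        raise ValueError(f"window ({window}) larger than contig ({n})")
    if step < 1 or window < 1:
        raise ValueError("window and step must be positive")
    view = np.lib.stride_tricks.sliding_window_view(track.depth, window)[::step]
    starts = np.arange(0, n - window + 1, step)
    return pd.DataFrame(
        {
            "start": starts,
            "end": starts + window,
            "min": view.min(axis=1),
            "mean": view.mean(axis=1),
            "max": view.max(axis=1),
        }
    )


def normalize_coverage(stats: pd.DataFrame) -> pd.DataFrame:
    """Add a ``ratio`` column: window mean / genome-wide median window mean.

    The median is a robust baseline: as long as duplicated blocks cover
    fewer than half the windows, it equals the background depth and the
    duplication shows up at ratio ~2.
    """
    if len(stats) == 0:
        raise ValueError("no windows to normalize")
    baseline = float(stats["mean"].median())
    if baseline <= 0:
        raise ValueError("all-zero coverage track: no baseline to normalize against")
    out = stats.copy()
    out["ratio"] = out["mean"] / baseline
    return out


def call_duplications(
    stats: pd.DataFrame,
    contig: str = "unknown",
    min_ratio: float = 1.5,
    min_length: int = 5000,
    merge_gap: int = 2000,
) -> List[DuplicationCall]:
    """Call duplicated intervals from normalized window ratios.

    Maximal runs of windows with ``ratio >= min_ratio`` become candidate
    calls with boundaries at the outermost qualifying window centers;
    candidates separated by at most ``merge_gap`` bp are merged, and
    merged calls shorter than ``min_length`` are discarded.
    """
    if "ratio" not in stats.columns:
        raise ValueError("stats must carry a 'ratio' column (run normalize_coverage)")
    if len(stats) == 0:
        return []
    qual = (stats["ratio"] >= min_ratio).to_numpy()
    if not qual.any():
        return []
    starts = stats["start"].to_numpy()
    window = int(stats["end"].iloc[0] - stats["start"].iloc[0])
    half = window // 2
    step = int(starts[1] - starts[0]) if len(starts) > 1 else window

    # maximal runs of qualifying windows
    idx = np.nonzero(qual)[0]
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    run_bounds = zip(np.insert(idx[breaks + 1], 0, idx[0]), np.append(idx[breaks], idx[-1]))
    raw: List[Tuple[int, int]] = []
    for first, last in run_bounds:
        # The threshold crossing lies between the outermost qualifying
        # window center and the neighboring non-qualifying one, so the
        # unbiased boundary estimate is the midpoint, half a step outward.
        s = int(starts[first]) + half - step // 2
        e = int(starts[last]) + half + step // 2
        s = max(s, 0)
        if e <= s:
            e = s + 1  # single-window run: keep a minimal interval
        raw.append((s, e))

    merged: List[List[int]] = []
    for s, e in raw:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    calls: List[DuplicationCall] = []
    for s, e in merged:
        if e - s < min_length:
            continue
        inside = (starts + half >= s) & (starts + half <= e) & qual
        mean_ratio = float(stats["ratio"].to_numpy()[inside].mean())
        calls.append(DuplicationCall(contig=contig, start=s, end=e, mean_ratio=mean_ratio))
    return calls


def _pileup_sites(pileup: pd.DataFrame):
    """Group a long-form pileup table by (contig, position)."""
    missing = [c for c in PILEUP_COLUMNS if c not in pileup.columns]
    if missing:
        raise ValueError(f"pileup table missing columns {missing}")
    return pileup.groupby(["contig", "pos"], sort=True)


def call_divergent_sites(
    pileup: pd.DataFrame,
    calls: Sequence[DuplicationCall],
    min_depth: int = 30,
    band: Tuple[float, float] = (0.3, 0.7),
) -> List[DivergenceCall]:
    """Report mid-fraction non-reference alleles inside called duplications.

    For each pileup site inside a duplication call with total depth of at
    least ``min_depth``, the non-reference allele with the highest count
    (ties broken by lexicographic allele order) is reported if its
    fraction of the site depth lies within ``band``.  Fixed differences
    (fraction ~1) and rare noise alleles fall outside the band and are
    not reported.
    """
    out: List[DivergenceCall] = []
    if len(pileup) == 0 or not calls:
        return out
    lo, hi = band
    for (contig, pos), site in _pileup_sites(pileup):
        enclosing = next(
            (c for c in calls if c.contig == contig and c.contains(int(pos))), None
        )
        if enclosing is None:
            continue
        depth = int(site["count"].sum())
        if depth < min_depth:
            continue
        ref = str(site["ref"].iloc[0])
        alt_rows = site[site["allele"] != ref]
        if len(alt_rows) == 0:
            continue
        alt_rows = alt_rows.sort_values(["count", "allele"], ascending=[False, True])
        alt = str(alt_rows["allele"].iloc[0])
        frac = float(alt_rows["count"].iloc[0]) / depth
        if lo <= frac <= hi:
            out.append(
                DivergenceCall(
                    contig=contig,
                    pos=int(pos),
                    ref=ref,
                    alt=alt,
                    depth=depth,
                    fraction=frac,
                    duplication=enclosing,
                )
            )
    return out


_STOP = "*"


def classify_effect(
    call: DivergenceCall,
    annotation: Union[GeneAnnotation, Sequence[GeneAnnotation]],
    reference: Optional[str] = None,
) -> str:
    """Minimal variant-effect label for a divergent site.

    Alleles use ``+SEQ`` for an insertion after the site and ``-SEQ`` for
    a deletion starting at the next base; any other allele is a base
    substitution.  Indels inside a CDS are ``frameshift`` when their
    length is not a multiple of 3, else ``inframe_indel``; substitutions
    are translated in frame (honoring strand and phase) into
    ``synonymous``, ``nonsense:<label>`` or ``missense:<label>`` with the
    conventional R276C-style label; sites outside every CDS are
    ``intergenic``.
    """
    genes = [annotation] if isinstance(annotation, GeneAnnotation) else list(annotation)
    gene = next(
        (g for g in genes if g.contig == call.contig and g.contains(call.pos)), None
    )
    if gene is None:
        return "intergenic"
    if gene.cds_length % 3 != 0:
        raise AnnotationError(
            f"{gene.gene_id}: CDS length {gene.cds_length} is not a multiple of 3"
        )

    if call.alt.startswith(("+", "-")):
        indel_len = len(call.alt) - 1
        if indel_len == 0:
            raise ValueError(f"empty indel allele {call.alt!r}")
        return "frameshift" if indel_len % 3 else "inframe_indel"

    if reference is None:
        raise ValueError("reference sequence required to classify substitutions")
    off = gene.cds_offset(call.pos)
    codon_idx = off // 3
    within = off % 3
    cds = gene.cds_sequence(reference)
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    alt_base = call.alt if gene.strand == "+" else str(Seq(call.alt).complement())
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_alt == aa_ref:
        return "synonymous"
    label = f"{aa_ref}{codon_idx + 1}{aa_alt}"
    return f"nonsense:{label}" if aa_alt == _STOP else f"missense:{label}"


def scan(
    track: CoverageTrack,
    pileup: Optional[pd.DataFrame] = None,
    annotations: Sequence[GeneAnnotation] = (),
    reference: Optional[str] = None,
    window: int = 1000,
    step: int = 100,
    min_ratio: float = 1.5,
    min_length: int = 5000,
    merge_gap: int = 2000,
    min_depth: int = 30,
    band: Tuple[float, float] = (0.3, 0.7),
) -> Tuple[List[DuplicationCall], List[DivergenceCall]]:
    """Full scanner pipeline: windows -> ratios -> duplications -> divergence."""
    stats = normalize_coverage(sliding_window_stats(track, window=window, step=step))
    dups = call_duplications(
        stats,
        contig=track.contig,
        min_ratio=min_ratio,
        min_length=min_length,
        merge_gap=merge_gap,
    )
    divs: List[DivergenceCall] = []
    if pileup is not None:
        divs = call_divergent_sites(pileup, dups, min_depth=min_depth, band=band)
        for d in divs:
            if annotations:
                d.effect = classify_effect(d, annotations, reference)
    return dups, divs
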