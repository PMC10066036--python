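"""GC-content landscape of phage genomes.

Mycobacteriophage genomes are typically GC-rich, matching their host, but
carry short locally GC-depressed regions; such regions are candidate binding
sites for AT-preferring nucleoid-associated proteins.  This module computes
overall and sliding-window GC fractions and calls contiguous low-GC regions,
plus a seeded synthetic genome generator with planted low-GC segments for
validating the caller.

Coordinates are 0-based half-open throughout; ambiguous (non-ACGT) bases
are excluded from both numerator and denominator of every GC fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "GCTrack",
    "LowGCRegion",
    "read_fasta",
    "gc_fraction",
    "gc_sliding",
    "low_gc_regions",
    "synthetic_genome",
]

_IUPAC = set("ACGTNRYSWKMBDHV")


@dataclass(frozen=True)
class GenomeSequence:
    identifier: str
    sequence: str                 # upper-case, validated IUPAC

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GCTrack:
    """Sliding-window GC fractions along one genome."""

    window: int
    step: int
    starts: np.ndarray            # 0-based window start coordinates
    gc: np.ndarray                # per-window GC fraction in [0, 1]
    genome_mean: float            # overall GC fraction of the genome

    @property
    def n_windows(self) -> int:
        return len(self.starts)


@dataclass(frozen=True)
class LowGCRegion:
    start: int                    # 0-based, half-open
    end: int
    mean_gc: float
    depth: float                  # percentage points below the genome mean


def _validate(seq: str, identifier: str) -> str:
    s = seq.upper().replace("\n", "").replace(" ", "")
    bad = set(s) - _IUPAC
    if bad:
        raise ValueError(f"{identifier}: invalid sequence characters {sorted(bad)}")
    if not s:
        raise ValueError(f"{identifier}: empty sequence")
    return s


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read (multi-)FASTA into validated, case-normalized genome records."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return [GenomeSequence(r.id, _validate(str(r.seq), r.id)) for r in records]


def _gc_at_counts(seq: str) -> tuple[int, int]:
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    return gc, at


def gc_fraction(seq: str | GenomeSequence) -> float:
    """(#G + #C) / (#A + #C + #G + #T), ambiguity codes excluded."""
    s = seq.sequence if isinstance(seq, GenomeSequence) else seq.upper()
    gc, at = _gc_at_counts(s)
    if gc + at == 0:
        raise ValueError("sequence has no unambiguous bases")
    return gc / (gc + at)


def gc_sliding(seq: str | GenomeSequence, window: int = 500,
               step: int = 100) -> GCTrack:
    """Sliding-window GC track with ``floor((L - window)/step) + 1`` windows."""
    s = seq.sequence if isinstance(seq, GenomeSequence) else seq.upper()
    L = len(s)
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be > 0")
    if window > L:
        raise ValueError(f"window {window} longer than sequence ({L} bp)")
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)
    is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_n = np.concatenate([[0], np.cumsum(is_acgt)])
    starts = np.arange(0, L - window + 1, step)
    gc = cum_gc[starts + window] - cum_gc[starts]
    n = cum_n[starts + window] - cum_n[starts]
    frac = np.divide(gc, n, out=np.full(len(starts), np.nan), where=n > 0)
    return GCTrack(window=window, step=step, starts=starts, gc=frac,
                   genome_mean=gc_fraction(s))


def low_gc_regions(track: GCTrack, drop_threshold: float = 8.0,
                   min_windows: int = 3) -> list[LowGCRegion]:
    """Merge runs of GC-depressed windows into candidate regions.

    A window qualifies when its GC fraction is at least ``drop_threshold``
    percentage points below the genome mean; runs of at least
    ``min_windows`` consecutive qualifying windows are merged into one
    region spanning from the first window's start to the last window's end.
    """
    if min_windows < 1:
        raise ValueError("min_windows must be >= 1")
    cut = track.genome_mean - drop_threshold / 100.0
    low = np.nan_to_num(track.gc, nan=np.inf) <= cut
    regions: list[LowGCRegion] = []
    i = 0
    n = len(low)
    while i < n:
        if low[i]:
            j = i
            while j + 1 < n and low[j + 1]:
                j += 1
            if j - i + 1 >= min_windows:
                start = int(track.starts[i])
                end = int(track.starts[j]) + track.window
                mean_gc = float(np.nanmean(track.gc[i:j + 1]))
                regions.append(LowGCRegion(
                    start=start, end=end, mean_gc=mean_gc,
                    depth=(track.genome_mean - mean_gc) * 100.0))
            i = j + 1
        else:
            i += 1
    return regions


def synthetic_genome(length: int = 40000, gc: float = 0.67,
                     low_gc_segments: tuple[tuple[int, int, float], ...] = (),
                     seed: int = 0) -> GenomeSequence:
    """Synthetic phage-like genome with planted low-GC segments.

    A stand-in for a real phage genome, generated base-by-base with
    P(G or C) = ``gc`` on the background and the given per-segment GC inside
    each planted ``(start, end, gc)`` interval.  Purely synthetic: it shares
    only coarse composition with any real genome.
    """
    rng = np.random.default_rng(seed)
    p = np.full(length, gc)
    for start, end, seg_gc in low_gc_segments:
        if not (0 <= start < end <= length):
            raise ValueError("planted segment outside the genome")
        p[start:end] = seg_gc
    is_gc = rng.random(length) < p
    strong = rng.integers(0, 2, length)        # G vs C
    weak = rng.integers(0, 2, length)          # A vs T
    bases = np.where(is_gc, np.where(strong == 1, ord("G"), ord("C")),
                     np.where(weak == 1, ord("A"), ord("T")))
    seq = bases.astype(np.uint8).tobytes().decode()
    return GenomeSequence("synthetic_phage_genome", seq)


def write_track(track: GCTrack, out_dir: str | Path,
                regions: list[LowGCRegion] | None = None,
                identifier: str = "genome") -> None:
    """Write gc_track.tsv, regions.bed (0-based) and summary.json."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "gc_track.tsv", "w") as fh:
        fh.write("start\tend\tgc\n")
        for s, g in zip(track.starts, track.gc):
            fh.write(f"{s}\t{s + track.window}\t{g:.6f}\n")
    if regions is not None:
        with open(out / "regions.bed", "w") as fh:
            for r in regions:
                fh.write(f"{identifier}\t{r.start}\t{r.end}\t"
                         f"gc={r.mean_gc:.4f};depth={r.depth:.2f}\n")
    with open(out / "summary.json", "w") as fh:
        json.dump({
            "identifier": identifier,
            "overall_gc_percent": round(track.genome_mean * 100.0, 4),
            "window": track.window, "step": track.step,
            "n_windows": track.n_windows,
            "n_low_gc_regions": None if regions is None else len(regions),
        }, fh, indent=2)
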