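"""Probe-burden screening of raw reads for aberrant-junction usage.

A probe set is built from aberrant junctions: for each junction the 40-nt
sequence centered on the aberrant 3' splice joint on the mRNA sense strand
(20 exonic nt either side of the spliced joint).  A sample's burden score is
the number of probes found at least once anywhere in its reads, allowing up
to two substitutions (Hamming distance; probes are searched on both
strands).  Scores grow with sequencing depth, so an ordinary least-squares
model ``score ~ coverage`` is fit excluding the top 1% of scores and the
residual is the depth-adjusted burden; samples whose residual reaches a
cutoff (given directly or anchored to a named reference sample) are flagged
as high-burden.

Two scoring engines are provided: a brute-force sliding Hamming scan, and a
seed-accelerated scan (the probe is partitioned into ``max_mismatch + 1``
exact seeds; by pigeonhole any occurrence within the mismatch budget
contains one exact seed, so the prefilter loses nothing and every candidate
is verified in full).  Both are exact; the brute-force path doubles as the
oracle in tests.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from Bio import SeqIO

from .junction_core import JunctionPair
from .synthetic_data import revcomp

__all__ = [
    "Probe",
    "ProbeSet",
    "build_probe_set",
    "find_probes",
    "score_sample",
    "adjust_scores",
    "flag_high",
    "PROBE_LEN",
]

PROBE_LEN = 40
_FLANK = PROBE_LEN // 2
_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class Probe:
    """A 40-nt probe; ``junction_ids`` keeps every source junction that
    produced this exact sequence (duplicates are deduplicated by sequence)."""

    id: str
    sequence: str
    junction_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != PROBE_LEN or not set(self.sequence) <= _ALPHABET:
            raise ValueError(f"probe {self.id}: need {PROBE_LEN} nt over ACGT")


class ProbeSet:
    def __init__(self, probes: Sequence[Probe]):
        ids = [p.id for p in probes]
        if len(set(ids)) != len(ids):
            raise ValueError("probe ids must be unique")
        self.probes = list(probes)

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self) -> Iterator[Probe]:
        return iter(self.probes)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for p in self.probes:
                fh.write(f">{p.id} {','.join(p.junction_ids)}\n{p.sequence}\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ProbeSet":
        probes = []
        for rec in SeqIO.parse(str(path), "fasta"):
            junction_ids = tuple(rec.description.split(maxsplit=1)[1].split(",")) \
                if " " in rec.description else (rec.id,)
            probes.append(Probe(rec.id, str(rec.seq).upper(), junction_ids))
        return cls(probes)


def _genome_mapping(genome) -> "object":
    if isinstance(genome, (str, Path)):
        import pyfaidx

        fa = pyfaidx.Fasta(str(genome))
        return {name: str(fa[name][:]) for name in fa.keys()}
    return genome


def build_probe_set(pairs: Iterable[JunctionPair], genome) -> ProbeSet:
    """40-nt probes across the aberrant splice joint, mRNA sense strand.

    For a plus-strand junction the probe is the last 20 exonic nt before the
    intron joined to the first 20 exonic nt after it; minus-strand probes
    are reverse-complemented to mRNA sense.  Junctions too close to a contig
    end are skipped with a warning.  Identical sequences from distinct
    junctions collapse to one probe retaining all source ids.
    """
    seqs = _genome_mapping(genome)
    by_seq: dict[str, list[str]] = {}
    for p in pairs:
        j = p.aberrant
        contig = seqs.get(j.chrom)
        if contig is None:
            raise KeyError(f"genome lacks contig {j.chrom!r}")
        left_start = j.donor - _FLANK - 1  # 0-based
        right_end = j.acceptor + _FLANK
        if left_start < 0 or right_end > len(contig):
            warnings.warn(f"junction {j.id} too close to contig end; probe skipped")
            continue
        probe = contig[left_start : j.donor - 1] + contig[j.acceptor : right_end]
        if j.strand == "-":
            probe = revcomp(probe)
        by_seq.setdefault(probe, []).append(p.id)
    probes = [
        Probe(id=f"probe{i:05d}", sequence=seq, junction_ids=tuple(ids))
        for i, (seq, ids) in enumerate(sorted(by_seq.items(), key=lambda kv: kv[1][0]))
    ]
    return ProbeSet(probes)


def _iter_read_seqs(fastq_paths: Iterable[str | Path]) -> Iterator[str]:
    for path in fastq_paths:
        path = str(path)
        opener = gzip.open if path.endswith(".gz") else open
        try:
            with opener(path, "rt") as fh:
                for rec in SeqIO.parse(fh, "fastq"):
                    yield str(rec.seq).upper()
        except (OSError, ValueError) as exc:
            raise ValueError(f"unreadable FASTQ {path}: {exc}") from None


def _hamming_hit(read: str, probe: str, max_mismatch: int) -> bool:
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    p = np.frombuffer(probe.encode(), dtype=np.uint8)
    if r.size < p.size:
        return False
    win = np.lib.stride_tricks.sliding_window_view(r, p.size)
    return bool((win != p).sum(axis=1).min() <= max_mismatch)


def _find_brute(reads: Iterable[str], probes: Sequence[Probe], max_mismatch: int) -> set[str]:
    pending = {p.id: (p.sequence, revcomp(p.sequence)) for p in probes}
    found: set[str] = set()
    for read in reads:
        if not pending:
            break
        for pid in list(pending):
            fwd, rev = pending[pid]
            if _hamming_hit(read, fwd, max_mismatch) or _hamming_hit(read, rev, max_mismatch):
                found.add(pid)
                del pending[pid]
    return found


def _seed_bounds(length: int, parts: int) -> list[tuple[int, int]]:
    cuts = np.linspace(0, length, parts + 1).round().astype(int)
    return [(int(cuts[i]), int(cuts[i + 1])) for i in range(parts)]


def _find_seeded(reads: Iterable[str], probes: Sequence[Probe], max_mismatch: int) -> set[str]:
    parts = max_mismatch + 1
    bounds = _seed_bounds(PROBE_LEN, parts)
    seed_lens = sorted({b - a for a, b in bounds})
    # seed -> list of (probe id, alignment offset, oriented probe sequence)
    index: dict[str, list[tuple[str, int, str]]] = {}
    for p in probes:
        for oriented in (p.sequence, revcomp(p.sequence)):
            for a, b in bounds:
                index.setdefault(oriented[a:b], []).append((p.id, a, oriented))

    pending = {p.id for p in probes}
    found: set[str] = set()
    for read in reads:
        if not pending:
            break
        L = len(read)
        for k in seed_lens:
            for pos in range(L - k + 1):
                hits = index.get(read[pos : pos + k])
                if not hits:
                    continue
                for pid, off, oriented in hits:
                    if pid not in pending:
                        continue
                    start = pos - off
                    if start < 0 or start + PROBE_LEN > L:
                        continue
                    window = read[start : start + PROBE_LEN]
                    mism = sum(a != b for a, b in zip(window, oriented))
                    if mism <= max_mismatch:
                        found.add(pid)
                        pending.discard(pid)
    return found


def find_probes(
    fastq_paths: Iterable[str | Path] | str | Path,
    probes: ProbeSet,
    max_mismatch: int = 2,
    method: str = "seed",
) -> set[str]:
    """Ids of probes occurring in the reads within the mismatch budget."""
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    reads = _iter_read_seqs(fastq_paths)
    if method == "brute":
        return _find_brute(reads, probes.probes, max_mismatch)
    if method == "seed":
        return _find_seeded(reads, probes.probes, max_mismatch)
    raise ValueError(f"unknown method {method!r}")


def score_sample(
    fastq_paths: Iterable[str | Path] | str | Path,
    probes: ProbeSet,
    max_mismatch: int = 2,
    method: str = "seed",
) -> int:
    """Burden score: number of probes found at least once (0..len(probes))."""
    return len(find_probes(fastq_paths, probes, max_mismatch=max_mismatch, method=method))


def adjust_scores(
    results: pd.DataFrame,
    score_col: str = "sbt_score",
    coverage_col: str = "coverage",
) -> pd.DataFrame:
    """Depth-adjust burden scores with OLS ``score ~ coverage``.

    The fit excludes samples at or above the 99th percentile of raw scores
    (the strict percentile: boundary ties are excluded); fitted values and
    residuals are then populated for all samples.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 samples to fit the coverage model")
    cov = results[coverage_col].to_numpy(dtype=float)
    if np.ptp(cov) == 0:
        raise ValueError("coverage has zero variance; cannot adjust scores")
    scores = results[score_col].to_numpy(dtype=float)
    thresh = np.quantile(scores, 0.99)
    fit_mask = scores < thresh
    if fit_mask.sum() < 3:  # degenerate score distribution; fit on everything
        fit_mask = np.ones_like(fit_mask)
    model = sm.OLS(scores[fit_mask], sm.add_constant(cov[fit_mask])).fit()
    fitted = model.params[0] + model.params[1] * cov
    out = results.copy()
    out["fitted"] = fitted
    out["residual"] = scores - fitted
    return out


def flag_high(
    results: pd.DataFrame,
    cutoff: float | None = None,
    anchor: str | None = None,
    sample_col: str = "sample_id",
) -> tuple[pd.DataFrame, float]:
    """Flag samples with residual >= cutoff (inclusive).

    ``cutoff`` may be given directly, or derived as the residual of a named
    anchor sample (which is then flagged itself, the boundary being
    inclusive).
    """
    if (cutoff is None) == (anchor is None):
        raise ValueError("give exactly one of cutoff or anchor")
    if anchor is not None:
        hit = results.loc[results[sample_col] == anchor, "residual"]
        if hit.empty:
            raise KeyError(f"anchor sample {anchor!r} not found")
        cutoff = float(hit.iloc[0])
    out = results.copy()
    out["flagged"] = out["residual"] >= cutoff
    return out, float(cutoff)
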