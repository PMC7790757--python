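"""Junction parsing, annotation pairing, splicing-index statistics.

The splicing index of an aberrant/canonical junction pair in one sample is

    SI = N_aberrant / (N_aberrant + N_canonical)

over unique split-read counts; it is undefined (missing) when neither
junction has a read.  Aberrant junctions are paired with their canonical
partner (the annotated junction sharing the opposite splice site) and
categorized by the signed distance of their novel end from the canonical
one, in transcript orientation (negative = upstream):

* ``proximal3`` / ``proximal5`` - novel acceptor / donor within 100 nt;
* ``distant``       - novel end more than 100 nt away;
* ``aberrant_exon`` - both ends are annotated splice sites of one gene but
  the junction itself is not annotated (e.g. exon skipping).

Junctions with two non-annotated ends and junctions connecting two
different genes (chimeric) are discarded.

Read-count expression gating uses per-sample quantiles of the canonical
junction counts: ``CQ`` (``AQ``) is the empirical-CDF value of a canonical
(aberrant) junction's count within the sample's canonical-count
distribution, making gating comparable across samples of different depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Junction",
    "JunctionPair",
    "ClassificationResult",
    "SIMatrix",
    "SelectionConfig",
    "read_sj_table",
    "classify_junctions",
    "compute_si",
    "compute_quantiles",
    "build_si_matrix",
    "select_junctions",
]

CATEGORIES = ("proximal3", "proximal5", "distant", "aberrant_exon")
PROXIMAL_MAX_NT = 100


@dataclass(frozen=True)
class Junction:
    """One splice junction in one sample.

    ``donor`` and ``acceptor`` are the first and last intronic bases
    (1-based, the ``SJ.out.tab`` convention); genomic order is enforced, so
    on the minus strand the biological donor is ``acceptor`` and vice versa.
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str = "."
    count: int = 0

    def __post_init__(self) -> None:
        if self.donor >= self.acceptor:
            raise ValueError(f"require donor < acceptor, got {self.donor} >= {self.acceptor}")
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.donor, self.acceptor)

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.donor}-{self.acceptor}"


@dataclass(frozen=True)
class JunctionPair:
    """An aberrant junction linked to its canonical partner."""

    aberrant: Junction
    canonical: Junction
    category: str
    gene_id: str
    distance: int | None = None  # transcript-oriented; negative = upstream
    side: str | None = None  # "three_prime" | "five_prime" | None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"bad category {self.category!r}")
        if self.category.startswith("proximal") and abs(self.distance) > PROXIMAL_MAX_NT:
            raise ValueError("proximal pair with |distance| > 100")

    @property
    def id(self) -> str:
        return self.aberrant.id


@dataclass
class ClassificationResult:
    canonical: list[Junction]
    pairs: list[JunctionPair]
    discarded: list[tuple[Junction, str]]


_STRAND_CODE = {0: ".", 1: "+", 2: "-"}


def read_sj_table(path: str | Path) -> list[Junction]:
    """Parse a STAR ``SJ.out.tab`` file (9 tab-separated columns).

    Strand codes 0/1/2 map to undetermined/+/-; the unique-mapping read
    count column is used (multi-mappers are ignored).  Malformed rows raise
    a :class:`ValueError` naming the line number; an empty file yields an
    empty list.
    """
    out: list[Junction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                strand = _STRAND_CODE[int(fields[3])]
                count = int(fields[6])
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: line {lineno}: malformed row ({exc})") from None
            out.append(Junction(chrom, start, end, strand, count))
    return out


def junctions_from_frame(table: pd.DataFrame) -> list[Junction]:
    """Convert an SJ-style DataFrame (as emitted by the simulator) to Junctions."""
    return [
        Junction(
            r.chrom,
            int(r.intron_start),
            int(r.intron_end),
            _STRAND_CODE[int(r.strand_code)],
            int(r.unique_reads),
        )
        for r in table.itertuples(index=False)
    ]


def collect_junctions(samples: Mapping[str, Sequence[Junction]]) -> list[Junction]:
    """Union of junction coordinates across samples, counts summed."""
    agg: dict[tuple, list] = {}
    for juncs in samples.values():
        for j in juncs:
            if j.key in agg:
                agg[j.key][1] += j.count
            else:
                agg[j.key] = [j.strand, j.count]
    return [Junction(c, s, e, strand, count) for (c, s, e), (strand, count) in agg.items()]


def annotated_introns(exons: pd.DataFrame) -> pd.DataFrame:
    """Introns implied by consecutive exons of each gene.

    ``exons`` needs columns ``gene_id, chrom, strand, start, end`` (1-based
    inclusive).  Returns ``gene_id, chrom, strand, start, end`` with
    intron coordinates (first/last intronic base).
    """
    required = {"gene_id", "chrom", "strand", "start", "end"}
    if exons is None or len(exons) == 0 or not required.issubset(exons.columns):
        raise ValueError("annotation must provide exons with gene_id/chrom/strand/start/end")
    rows = []
    for gene_id, sub in exons.groupby("gene_id", sort=True):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for i in range(len(sub) - 1):
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": sub["chrom"].iloc[0],
                    "strand": sub["strand"].iloc[0],
                    "start": int(ends[i]) + 1,
                    "end": int(starts[i + 1]) - 1,
                }
            )
    return pd.DataFrame(rows)


def classify_junctions(
    junctions: Iterable[Junction],
    exons: pd.DataFrame,
    canonical_counts: Mapping[str, float] | None = None,
) -> ClassificationResult:
    """Split observed junctions into canonical / paired-aberrant / discarded.

    A junction is canonical iff both ends match an annotated intron of one
    gene.  A half-canonical junction shares exactly one end with an
    annotated intron; its canonical partner is the nearest annotated
    junction sharing that end (ties broken toward the partner with higher
    ``canonical_counts`` value when given, else lower coordinate).
    Undetermined-strand junctions inherit the gene strand upon matching.
    """
    introns = annotated_introns(exons)
    ann: dict[tuple, tuple[str, str]] = {}  # (chrom,s,e) -> (gene, strand)
    by_start: dict[tuple, list] = {}  # (chrom,s) -> [(gene, strand, e), ...]
    by_end: dict[tuple, list] = {}
    for r in introns.itertuples(index=False):
        key = (r.chrom, int(r.start), int(r.end))
        ann.setdefault(key, (r.gene_id, r.strand))
        by_start.setdefault((r.chrom, int(r.start)), []).append((r.gene_id, r.strand, int(r.end)))
        by_end.setdefault((r.chrom, int(r.end)), []).append((r.gene_id, r.strand, int(r.start)))

    def partner_pick(cands, novel, make_id):
        # nearest annotated end; ties toward higher cohort count, then lower coord
        best = None
        for gene, strand, coord in cands:
            cnt = float((canonical_counts or {}).get(make_id(coord), 0.0))
            key = (abs(coord - novel), -cnt, coord)
            if best is None or key < best[0]:
                best = (key, (gene, strand, coord))
        return best[1]

    canonical: list[Junction] = []
    pairs: list[JunctionPair] = []
    discarded: list[tuple[Junction, str]] = []

    for j in junctions:
        key = j.key
        if key in ann:
            gene, strand = ann[key]
            canonical.append(Junction(j.chrom, j.donor, j.acceptor, strand, j.count))
            continue
        s_hits = by_start.get((j.chrom, j.donor), [])
        e_hits = by_end.get((j.chrom, j.acceptor), [])
        s_genes = {g for g, _, _ in s_hits}
        e_genes = {g for g, _, _ in e_hits}
        if s_hits and e_hits:
            common = sorted(s_genes & e_genes)
            if not common:
                discarded.append((j, "chimeric"))
                continue
            gene = common[0]
            strand = next(st for g, st, _ in s_hits if g == gene)
            # pair with the annotated intron sharing the start (deterministic)
            _, _, e_can = partner_pick(
                [h for h in s_hits if h[0] == gene],
                j.acceptor,
                lambda e: f"{j.chrom}:{j.donor}-{e}",
            )
            pairs.append(
                JunctionPair(
                    aberrant=Junction(j.chrom, j.donor, j.acceptor, strand, j.count),
                    canonical=Junction(j.chrom, j.donor, e_can, strand),
                    category="aberrant_exon",
                    gene_id=gene,
                    distance=None,
                    side=None,
                )
            )
            continue
        if s_hits:
            gene, strand, e_can = partner_pick(
                s_hits, j.acceptor, lambda e: f"{j.chrom}:{j.donor}-{e}"
            )
            novel, can = j.acceptor, e_can
            side = "three_prime" if strand == "+" else "five_prime"
        elif e_hits:
            gene, strand, s_can = partner_pick(
                e_hits, j.donor, lambda s: f"{j.chrom}:{s}-{j.acceptor}"
            )
            novel, can = j.donor, s_can
            side = "five_prime" if strand == "+" else "three_prime"
        else:
            discarded.append((j, "both_noncanonical"))
            continue
        d_genomic = novel - can
        distance = d_genomic if strand == "+" else -d_genomic
        if abs(distance) <= PROXIMAL_MAX_NT:
            category = "proximal3" if side == "three_prime" else "proximal5"
        else:
            category = "distant"
        can_j = (
            Junction(j.chrom, j.donor, e_can, strand)
            if s_hits
            else Junction(j.chrom, s_can, j.acceptor, strand)
        )
        pairs.append(
            JunctionPair(
                aberrant=Junction(j.chrom, j.donor, j.acceptor, strand, j.count),
                canonical=can_j,
                category=category,
                gene_id=gene,
                distance=int(distance),
                side=side,
            )
        )
    return ClassificationResult(canonical=canonical, pairs=pairs, discarded=discarded)


def compute_si(a_count, c_count):
    """SI = a / (a + c); NaN (missing) where a + c == 0.

    Accepts scalars or array-likes; negative counts raise.
    """
    a = np.asarray(a_count, dtype=float)
    c = np.asarray(c_count, dtype=float)
    if (a < 0).any() or (c < 0).any():
        raise ValueError("counts must be non-negative")
    tot = a + c
    with np.errstate(invalid="ignore", divide="ignore"):
        si = np.where(tot > 0, a / np.where(tot > 0, tot, 1.0), np.nan)
    if si.ndim == 0:
        return float(si)
    return si


def compute_quantiles(canonical_counts, query_counts):
    """Empirical-CDF quantiles of counts within a sample.

    The quantile of a count ``x`` is the fraction of the sample's canonical
    junction counts ``<= x`` (right-continuous eCDF, ties counted).  Raises
    if the sample has no canonical junction with a positive count.
    """
    ref = np.sort(np.asarray(canonical_counts, dtype=float))
    if ref.size == 0 or not (ref > 0).any():
        raise ValueError("sample has no expressed canonical junction")
    q = np.searchsorted(ref, np.asarray(query_counts, dtype=float), side="right") / ref.size
    return q


@dataclass
class SIMatrix:
    """Samples x junction-pairs SI/AQ/CQ matrices with group labels."""

    si: pd.DataFrame
    aq: pd.DataFrame
    cq: pd.DataFrame
    groups: pd.Series | None = None
    pairs: dict[str, JunctionPair] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in (("aq", self.aq), ("cq", self.cq)):
            vals = m.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
                raise ValueError(f"{name} values must lie in [0, 1]")
        si = self.si.to_numpy(dtype=float)
        ok = np.isnan(si) | ((si >= 0) & (si <= 1))
        if not ok.all():
            raise ValueError("SI values must lie in [0, 1] or be missing")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.si.index)

    @property
    def junction_ids(self) -> list[str]:
        return list(self.si.columns)

    def restrict(self, junction_ids: Sequence[str]) -> "SIMatrix":
        cols = [j for j in junction_ids if j in self.si.columns]
        return SIMatrix(
            si=self.si[cols],
            aq=self.aq[cols],
            cq=self.cq[cols],
            groups=self.groups,
            pairs={k: v for k, v in self.pairs.items() if k in cols},
        )


def build_si_matrix(
    sample_junctions: Mapping[str, Sequence[Junction]],
    pairs: Sequence[JunctionPair],
    canonical: Iterable[Junction | tuple[str, int, int]],
    groups: pd.Series | Mapping[str, str] | None = None,
) -> SIMatrix:
    """Assemble the SI/AQ/CQ matrix for a cohort.

    ``canonical`` enumerates the annotated canonical junctions whose
    observed counts define each sample's quantile reference distribution.
    Junctions absent from a sample's table count as zero reads.
    """
    can_keys = [j.key if isinstance(j, Junction) else tuple(j) for j in canonical]
    pair_ids = [p.id for p in pairs]
    ab_keys = [p.aberrant.key for p in pairs]
    pc_keys = [p.canonical.key for p in pairs]

    samples = list(sample_junctions)
    si = np.empty((len(samples), len(pairs)))
    aq = np.empty_like(si)
    cq = np.empty_like(si)
    for i, s in enumerate(samples):
        counts = {j.key: j.count for j in sample_junctions[s]}
        ref = np.array([counts.get(k, 0) for k in can_keys], dtype=float)
        ref = ref[ref > 0]
        if ref.size == 0:
            raise ValueError(f"sample {s!r} has no expressed canonical junction")
        a = np.array([counts.get(k, 0) for k in ab_keys], dtype=float)
        c = np.array([counts.get(k, 0) for k in pc_keys], dtype=float)
        si[i] = compute_si(a, c)
        aq[i] = compute_quantiles(ref, a)
        cq[i] = compute_quantiles(ref, c)

    if groups is not None and not isinstance(groups, pd.Series):
        groups = pd.Series(groups)
    if groups is not None:
        groups = groups.reindex(samples)
    return SIMatrix(
        si=pd.DataFrame(si, index=samples, columns=pair_ids),
        aq=pd.DataFrame(aq, index=samples, columns=pair_ids),
        cq=pd.DataFrame(cq, index=samples, columns=pair_ids),
        groups=groups,
        pairs={p.id: p for p in pairs},
    )


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the junction-selection rules.

    A junction is kept iff at least one sample satisfies
    ``SI >= si_min and AQ >= aq_min and CQ >= cq_min``.  Optional extra
    rules: the ubiquitous-expression requirement (canonical partner with
    ``CQ >= ubiquity_cq`` in at least ``ubiquity_frac`` of samples) and the
    control-group exclusion (drop junctions whose canonical partner is not
    expressed in controls, median control ``CQ < control_cq_min``, or whose
    aberrant form is already well expressed in controls, max control
    ``AQ > control_aq_max``).
    """

    si_min: float = 0.15
    aq_min: float = 0.4
    cq_min: float = 0.5
    ubiquity_cq: float | None = None
    ubiquity_frac: float | None = None
    control_labels: tuple[str, ...] = ()
    control_cq_min: float | None = None
    control_aq_max: float | None = None

    def __post_init__(self) -> None:
        for name in ("si_min", "aq_min", "cq_min", "ubiquity_cq", "ubiquity_frac",
                     "control_cq_min", "control_aq_max"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def select_junctions(matrix: SIMatrix, cfg: SelectionConfig) -> list[str]:
    """Apply the selection rules; returns kept junction ids in column order."""
    si = matrix.si.to_numpy(dtype=float)
    aq = matrix.aq.to_numpy(dtype=float)
    cq = matrix.cq.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        hit = (si >= cfg.si_min) & (aq >= cfg.aq_min) & (cq >= cfg.cq_min)
    keep = np.nansum(hit, axis=0) > 0

    if cfg.ubiquity_cq is not None and cfg.ubiquity_frac is not None:
        frac = (cq >= cfg.ubiquity_cq).mean(axis=0)
        keep &= frac >= cfg.ubiquity_frac

    if cfg.control_labels and (cfg.control_cq_min is not None or cfg.control_aq_max is not None):
        if matrix.groups is None:
            raise ValueError("control exclusion requires group labels on the matrix")
        mask = matrix.groups.isin(cfg.control_labels).to_numpy()
        if mask.any():
            if cfg.control_cq_min is not None:
                keep &= np.median(cq[mask], axis=0) >= cfg.control_cq_min
            if cfg.control_aq_max is not None:
                keep &= aq[mask].max(axis=0) <= cfg.control_aq_max

    return [j for j, k in zip(matrix.si.columns, keep) if k]
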