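"""Readers and writers for the pipeline's tab-separated interchange files."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .junction_core import Junction, JunctionPair, SIMatrix

PAIR_COLUMNS = [
    "pair_id",
    "chrom",
    "aberrant_start",
    "aberrant_end",
    "canonical_start",
    "canonical_end",
    "strand",
    "gene_id",
    "category",
    "side",
    "distance",
]


def write_pairs(pairs, path: str | Path) -> None:
    rows = [
        {
            "pair_id": p.id,
            "chrom": p.aberrant.chrom,
            "aberrant_start": p.aberrant.donor,
            "aberrant_end": p.aberrant.acceptor,
            "canonical_start": p.canonical.donor,
            "canonical_end": p.canonical.acceptor,
            "strand": p.aberrant.strand,
            "gene_id": p.gene_id,
            "category": p.category,
            "side": p.side if p.side is not None else "",
            "distance": p.distance if p.distance is not None else "",
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> list[JunctionPair]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    pairs = []
    for r in df.itertuples(index=False):
        pairs.append(
            JunctionPair(
                aberrant=Junction(r.chrom, int(r.aberrant_start), int(r.aberrant_end), r.strand),
                canonical=Junction(r.chrom, int(r.canonical_start), int(r.canonical_end), r.strand),
                category=r.category,
                gene_id=r.gene_id,
                distance=int(r.distance) if r.distance != "" else None,
                side=r.side or None,
            )
        )
    return pairs


def write_si_matrix(matrix: SIMatrix, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.si.to_csv(out / "si.tsv", sep="\t")
    matrix.aq.to_csv(out / "aq.tsv", sep="\t")
    matrix.cq.to_csv(out / "cq.tsv", sep="\t")
    if matrix.groups is not None:
        matrix.groups.rename("group").to_csv(out / "groups.tsv", sep="\t")


def read_si_matrix(indir: str | Path, pairs=None) -> SIMatrix:
    ind = Path(indir)
    si = pd.read_csv(ind / "si.tsv", sep="\t", index_col=0)
    aq = pd.read_csv(ind / "aq.tsv", sep="\t", index_col=0)
    cq = pd.read_csv(ind / "cq.tsv", sep="\t", index_col=0)
    groups = None
    if (ind / "groups.tsv").exists():
        groups = pd.read_csv(ind / "groups.tsv", sep="\t", index_col=0)["group"]
    return SIMatrix(
        si=si, aq=aq, cq=cq, groups=groups,
        pairs={p.id: p for p in pairs} if pairs else {},
    )


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_sj_dir(sj_dir: str | Path) -> Mapping[str, list[Junction]]:
    """All ``*.SJ.out.tab`` / ``*.tab`` files of a directory, keyed by sample."""
    from .junction_core import read_sj_table

    out = {}
    for path in sorted(Path(sj_dir).glob("*.tab")):
        sample = path.name.removesuffix(".SJ.out.tab").removesuffix(".tab")
        out[sample] = read_sj_table(path)
    return out
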