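"""Synthetic cohorts with planted cryptic 3'-splice-site usage.

This module generates everything the downstream analysis consumes, with the
statistical structure the method assumes, so the whole pipeline is testable
without any external download:

* a toy multi-gene genome (FASTA) whose introns carry an ``AG`` cryptic
  acceptor 10-30 nt upstream (transcript orientation) of every canonical
  acceptor;
* per-sample splice-junction count tables in the STAR ``SJ.out.tab`` dialect,
  with negative-binomial canonical counts, per-sample library-size
  heterogeneity, and aberrant counts thinned binomially so that the expected
  splicing index (SI) equals a configured value;
* junction-spanning FASTQ reads for the probe-burden stage.

The cohort layout emulates a tumor series: a large control group plus two
small groups carrying distinct splicing-factor alterations that elevate SI
at a planted set of "sensitive" cryptic acceptors, a subset of which is
shared between the two altered groups.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._seeds import stage_rng

__all__ = [
    "SimConfig",
    "GeneModel",
    "SimTruth",
    "Cohort",
    "make_gene_model",
    "simulate_cohort",
    "simulate_reads",
    "write_fastq",
    "write_genome_fasta",
    "SJ_COLUMNS",
]

SJ_COLUMNS = [
    "chrom",
    "intron_start",
    "intron_end",
    "strand_code",
    "motif",
    "annotated",
    "unique_reads",
    "multi_reads",
    "overhang",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
#: spacer between genes / at contig ends; also guarantees room for read flanks
_SPACER = 200


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults reproduce the cohort geometry of the lung-adenocarcinoma
    comparison the pipeline is built for: 400 controls versus two small
    altered groups (6 and 5 samples), 90 sensitive cryptic acceptors of
    which 50 respond in both groups and 20 in each single group, a mean SI
    of 0.3 at responding junctions, and cryptic offsets uniform on 10-30 nt
    upstream of the canonical acceptor.
    """

    n_genes: int = 120
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_len: tuple[int, int] = (80, 200)
    intron_len: tuple[int, int] = (150, 400)
    n_controls: int = 400
    n_groupA: int = 6
    n_groupB: int = 5
    n_sensitive_junctions: int = 90
    frac_shared: float = 5.0 / 9.0
    si_effect: float = 0.3
    si_background: float = 0.01
    nb_dispersion: float = 0.15
    base_mean: float = 150.0
    base_log_sd: float = 0.6
    coverage_range: tuple[float, float] = (0.5, 2.0)
    cryptic_offset_range: tuple[int, int] = (10, 30)
    group_labels: tuple[str, str, str] = ("control", "groupA", "groupB")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_sensitive_junctions < 1:
            raise ValueError("counts must be >= 1")
        if self.exons_per_gene[0] < 2:
            raise ValueError("genes need at least two exons to have a junction")
        if not (0.0 <= self.si_background < self.si_effect <= 1.0):
            raise ValueError("require 0 <= si_background < si_effect <= 1")
        if not (0.0 <= self.frac_shared <= 1.0):
            raise ValueError("frac_shared must be in [0, 1]")
        lo, hi = self.cryptic_offset_range
        if not (5 <= lo <= hi <= 100):
            raise ValueError("cryptic_offset_range must lie within 5-100 nt")
        if self.intron_len[0] <= hi + 10:
            raise ValueError(
                "intron shorter than cryptic offset: min intron length must "
                f"exceed max cryptic offset + 10 ({hi + 10})"
            )
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.coverage_range[0] <= 0:
            raise ValueError("coverage multipliers must be positive")


@dataclass
class GeneModel:
    """A toy genome plus its exon annotation and junction catalog.

    ``junctions`` has one row per canonical intron with the coordinates of
    its planted cryptic acceptor: columns ``junction_id, gene_id, chrom,
    strand, start, end, cryptic_start, cryptic_end, offset`` where
    ``start``/``end`` are the first/last intronic bases (1-based, as in
    ``SJ.out.tab``).
    """

    genome: dict[str, str]
    exons: pd.DataFrame
    junctions: pd.DataFrame

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive genomic slice (plus strand)."""
        return self.genome[chrom][start - 1 : end]


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    sensitive: pd.DataFrame  # junction_id, assignment, cryptic_id, offset
    sample_groups: pd.Series  # sample id -> group label
    si_effect: float
    si_background: float

    @property
    def sensitive_junction_ids(self) -> set[str]:
        return set(self.sensitive["junction_id"])

    def ids_for(self, assignment: str) -> set[str]:
        sub = self.sensitive[self.sensitive["assignment"] == assignment]
        return set(sub["junction_id"])


@dataclass
class Cohort:
    """A simulated cohort: SJ tables, metadata, truth and raw count matrices."""

    config: SimConfig
    model: GeneModel
    sj_tables: dict[str, pd.DataFrame]
    metadata: pd.DataFrame  # sample_id, group, coverage (total split reads), multiplier
    truth: SimTruth
    canonical_counts: pd.DataFrame  # samples x junction_id
    aberrant_counts: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        (out / "sj").mkdir(parents=True, exist_ok=True)
        write_genome_fasta(self.model.genome, out / "genome.fa")
        self.model.exons.to_csv(out / "exons.tsv", sep="\t", index=False)
        self.model.junctions.to_csv(out / "junctions.tsv", sep="\t", index=False)
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        for sample, table in self.sj_tables.items():
            table.to_csv(out / "sj" / f"{sample}.SJ.out.tab", sep="\t", index=False, header=False)
        truth = {
            "si_effect": self.truth.si_effect,
            "si_background": self.truth.si_background,
            "sample_groups": self.truth.sample_groups.to_dict(),
            "sensitive": self.truth.sensitive.to_dict(orient="records"),
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))


def write_genome_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def make_gene_model(config: SimConfig) -> GeneModel:
    """Build the toy genome and annotation for a configuration.

    Every canonical intron receives donor/acceptor dinucleotides (GT..AG in
    transcript orientation) and a cryptic ``AG`` acceptor ``offset`` nt
    upstream of the canonical acceptor, strand-aware: on the minus strand
    "upstream of the acceptor" means larger genomic coordinates and the
    acceptor dinucleotide appears as ``CT`` on the plus-strand reference.
    """
    rng = stage_rng(config.seed, "genome")
    ex_lo, ex_hi = config.exons_per_gene
    el_lo, el_hi = config.exon_len
    il_lo, il_hi = config.intron_len
    off_lo, off_hi = config.cryptic_offset_range

    exon_rows: list[dict] = []
    junc_rows: list[dict] = []
    chrom = "chr1"
    pos = _SPACER + 1  # next unoccupied 1-based position

    for g in range(config.n_genes):
        gene_id = f"g{g:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(ex_lo, ex_hi + 1))
        exon_lens = rng.integers(el_lo, el_hi + 1, size=n_ex)
        intron_lens = rng.integers(il_lo, il_hi + 1, size=n_ex - 1)
        starts = []
        cur = pos
        for i in range(n_ex):
            starts.append(cur)
            exon_rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "strand": strand,
                    "exon": i,
                    "start": cur,
                    "end": cur + int(exon_lens[i]) - 1,
                }
            )
            cur += int(exon_lens[i])
            if i < n_ex - 1:
                intron_start = cur
                intron_end = cur + int(intron_lens[i]) - 1
                offset = int(rng.integers(off_lo, off_hi + 1))
                if strand == "+":
                    cryptic = (intron_start, intron_end - offset)
                else:
                    cryptic = (intron_start + offset, intron_end)
                junc_rows.append(
                    {
                        "junction_id": f"{chrom}:{intron_start}-{intron_end}",
                        "gene_id": gene_id,
                        "chrom": chrom,
                        "strand": strand,
                        "start": intron_start,
                        "end": intron_end,
                        "cryptic_start": cryptic[0],
                        "cryptic_end": cryptic[1],
                        "offset": offset,
                    }
                )
                cur = intron_end + 1
        pos = cur + _SPACER

    total_len = pos + _SPACER
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=total_len)

    def put(p: int, s: str) -> None:  # 1-based
        seq[p - 1 : p - 1 + len(s)] = np.frombuffer(s.encode(), dtype="S1")

    for j in junc_rows:
        s, e = j["start"], j["end"]
        if j["strand"] == "+":
            put(s, "GT")
            put(e - 1, "AG")
            put(j["cryptic_end"] - 1, "AG")
        else:
            put(s, "CT")  # acceptor AG read on the minus strand
            put(e - 1, "AC")  # donor GT read on the minus strand
            put(j["cryptic_start"], "CT")

    genome = {chrom: seq.tobytes().decode()}
    exons = pd.DataFrame(exon_rows)
    junctions = pd.DataFrame(junc_rows)
    if len(junctions) < config.n_sensitive_junctions:
        raise ValueError(
            f"model has {len(junctions)} junctions but "
            f"{config.n_sensitive_junctions} sensitive ones requested"
        )
    return GeneModel(genome=genome, exons=exons, junctions=junctions)


def _sample_names(config: SimConfig) -> tuple[list[str], list[str]]:
    ctl, ga, gb = config.group_labels
    names, labels = [], []
    for i in range(config.n_controls):
        names.append(f"ctl{i:03d}")
        labels.append(ctl)
    for i in range(config.n_groupA):
        names.append(f"A{i:02d}")
        labels.append(ga)
    for i in range(config.n_groupB):
        names.append(f"B{i:02d}")
        labels.append(gb)
    return names, labels


def simulate_cohort(config: SimConfig, model: GeneModel | None = None) -> Cohort:
    """Draw per-sample junction counts and emit SJ.out.tab-style tables.

    Canonical-junction totals are negative binomial with mean
    ``base_expression * coverage multiplier`` and dispersion
    ``nb_dispersion`` (variance mu + d*mu^2); the aberrant split-read count
    is a binomial thinning of the total so the expected SI equals
    ``si_effect`` in a sensitive junction's elevated group(s) and
    ``si_background`` everywhere else.
    """
    if config.n_controls + config.n_groupA + config.n_groupB == 0:
        raise ValueError("all group sizes are zero")
    if model is None:
        model = make_gene_model(config)

    junc = model.junctions
    n_j = len(junc)
    names, labels = _sample_names(config)
    n_s = len(names)
    ctl, ga, gb = config.group_labels

    expr_rng = stage_rng(config.seed, "expression")
    base_mu = expr_rng.lognormal(np.log(config.base_mean), config.base_log_sd, size=n_j)

    rng = stage_rng(config.seed, "cohort")
    # sensitive-junction assignment
    sens_idx = rng.choice(n_j, size=config.n_sensitive_junctions, replace=False)
    n_shared = int(round(config.frac_shared * config.n_sensitive_junctions))
    n_rest = config.n_sensitive_junctions - n_shared
    n_a = n_rest // 2 + n_rest % 2
    assignments = ["shared"] * n_shared + ["A_specific"] * n_a + ["B_specific"] * (n_rest - n_a)
    sensitive = pd.DataFrame(
        {
            "junction_id": junc["junction_id"].to_numpy()[sens_idx],
            "assignment": assignments,
            "cryptic_id": [
                f"{c}:{s}-{e}"
                for c, s, e in zip(
                    junc["chrom"].to_numpy()[sens_idx],
                    junc["cryptic_start"].to_numpy()[sens_idx],
                    junc["cryptic_end"].to_numpy()[sens_idx],
                )
            ],
            "offset": junc["offset"].to_numpy()[sens_idx],
        }
    )

    multipliers = rng.uniform(*config.coverage_range, size=n_s)

    # SI rate matrix (samples x junctions)
    si = np.full((n_s, n_j), config.si_background)
    labels_arr = np.asarray(labels)
    for row in sensitive.itertuples(index=False):
        j = int(np.flatnonzero(junc["junction_id"].to_numpy() == row.junction_id)[0])
        if row.assignment in ("shared", "A_specific"):
            si[labels_arr == ga, j] = config.si_effect
        if row.assignment in ("shared", "B_specific"):
            si[labels_arr == gb, j] = config.si_effect

    mu = np.outer(multipliers, base_mu)
    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        totals = rng.negative_binomial(r, r / (r + mu))
    else:
        totals = rng.poisson(mu)
    aberrant = rng.binomial(totals, si)
    canonical = totals - aberrant

    strand_code = np.where(junc["strand"].to_numpy() == "+", 1, 2)
    motif = np.where(junc["strand"].to_numpy() == "+", 1, 2)  # GT/AG vs CT/AC

    sj_tables: dict[str, pd.DataFrame] = {}
    for i, sample in enumerate(names):
        rows = []
        can_mask = canonical[i] > 0
        ab_mask = aberrant[i] > 0
        can = pd.DataFrame(
            {
                "chrom": junc["chrom"].to_numpy()[can_mask],
                "intron_start": junc["start"].to_numpy()[can_mask],
                "intron_end": junc["end"].to_numpy()[can_mask],
                "strand_code": strand_code[can_mask],
                "motif": motif[can_mask],
                "annotated": 1,
                "unique_reads": canonical[i][can_mask],
                "multi_reads": 0,
                "overhang": 50,
            }
        )
        ab = pd.DataFrame(
            {
                "chrom": junc["chrom"].to_numpy()[ab_mask],
                "intron_start": junc["cryptic_start"].to_numpy()[ab_mask],
                "intron_end": junc["cryptic_end"].to_numpy()[ab_mask],
                "strand_code": strand_code[ab_mask],
                "motif": motif[ab_mask],
                "annotated": 0,
                "unique_reads": aberrant[i][ab_mask],
                "multi_reads": 0,
                "overhang": 50,
            }
        )
        table = pd.concat([can, ab], ignore_index=True)
        table = table.sort_values(["chrom", "intron_start", "intron_end"], kind="mergesort")
        sj_tables[sample] = table.reset_index(drop=True)[SJ_COLUMNS]

    metadata = pd.DataFrame(
        {
            "sample_id": names,
            "group": labels,
            "coverage": totals.sum(axis=1),
            "multiplier": multipliers,
        }
    )
    truth = SimTruth(
        sensitive=sensitive,
        sample_groups=pd.Series(labels, index=names, name="group"),
        si_effect=config.si_effect,
        si_background=config.si_background,
    )
    jid = junc["junction_id"].tolist()
    return Cohort(
        config=config,
        model=model,
        sj_tables=sj_tables,
        metadata=metadata,
        truth=truth,
        canonical_counts=pd.DataFrame(canonical, index=names, columns=jid),
        aberrant_counts=pd.DataFrame(aberrant, index=names, columns=jid),
    )


PROBE_LEN = 40  # matched by the burden-screen probe length


def simulate_reads(
    sj_table: pd.DataFrame,
    model: GeneModel,
    read_len: int = 100,
    n_background: int = 0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Junction-spanning reads (plus optional genomic background reads).

    Each junction with ``k`` unique split reads contributes exactly ``k``
    reads whose center sits on the spliced joint (mRNA sense strand), so
    that when ``error_rate`` is zero every read contains the 40-mer probe of
    its junction verbatim.  Substitution errors are applied uniformly per
    base at ``error_rate``.
    """
    if read_len < PROBE_LEN:
        raise ValueError(f"read_len must be >= probe length ({PROBE_LEN})")
    rng = stage_rng(seed, "reads")
    left_len = read_len // 2
    right_len = read_len - left_len
    reads: list[tuple[str, str]] = []
    bases = np.frombuffer(b"ACGT", dtype="S1")

    def maybe_mutate(seq: str) -> str:
        if error_rate <= 0:
            return seq
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        hit = np.flatnonzero(rng.random(len(arr)) < error_rate)
        for i in hit:
            choices = bases[bases != arr[i]]
            arr[i] = rng.choice(choices)
        return arr.tobytes().decode()

    for row in sj_table.itertuples(index=False):
        chrom = row.chrom
        s, e = int(row.intron_start), int(row.intron_end)
        strand = "+" if int(row.strand_code) == 1 else "-"
        left = model.sequence(chrom, s - left_len, s - 1)
        right = model.sequence(chrom, e + 1, e + right_len)
        joint = left + right
        if strand == "-":
            joint = revcomp(joint)
        for i in range(int(row.unique_reads)):
            reads.append((f"jx|{chrom}:{s}-{e}|{i}", maybe_mutate(joint)))

    for b in range(n_background):
        chrom = rng.choice(list(model.genome))
        contig = model.genome[chrom]
        start = int(rng.integers(0, len(contig) - read_len + 1))
        seq = contig[start : start + read_len]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append((f"bg|{chrom}:{start + 1}|{b}", maybe_mutate(seq)))
    return reads


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
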