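"""Seeded synthetic inputs (genomes, annotations, VCFs, proteomes) and
brute-force oracles, so every pipeline stage is testable offline.

All generators are pure functions of their parameters and seed; every
oracle refuses inputs beyond its size guard instead of silently running.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._alphabet import AA20, DNA4, Alphabet, revcomp
from .mutation_maps import CODON_TABLE
from .sequence_io import ContigSequence, GeneModel, GNOMAD_POPULATIONS, VariantRecord

__all__ = [
    "FixtureSpec",
    "synth_genome",
    "synth_annotation",
    "synth_vcf",
    "synth_proteome",
    "synth_cds",
    "write_gff3",
    "write_vcf",
    "oracle_nullomers",
    "oracle_mutation_scan",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    genome_length: int = 10000
    gc: float = 0.5
    n_runs: tuple = ((0.4, 50),)  # (relative position, run length)
    planted_absent_motifs: tuple = ()
    n_genes: int = 2
    n_variants: int = 20
    populations: tuple = GNOMAD_POPULATIONS
    n_proteins: int = 20
    protein_length: tuple = (50, 200)


def _find_hit(seq: str, motifs: Sequence[str], both: bool) -> tuple[int, int] | None:
    for m in motifs:
        targets = {m, revcomp(m)} if both else {m}
        for t in targets:
            i = seq.find(t)
            if i >= 0:
                return i, len(t)
    return None


def synth_genome(
    length: int,
    gc: float = 0.5,
    n_runs: Sequence[tuple] = (),
    planted_absent_motifs: Sequence[str] = (),
    seed: int = 0,
    strand_mode: str = "both",
    contig_id: str = "chr1",
    max_repair: int = 10000,
) -> ContigSequence:
    """Random genome at the requested GC with N runs and guaranteed-absent
    planted motifs.

    Exclusion is by local repair: the window containing a motif hit (or,
    in both-strand mode, a hit of its reverse complement) is resampled
    until no hit remains, preserving global composition.
    """
    for m in planted_absent_motifs:
        if len(m) < 2:
            raise ValueError(f"planted motif {m!r} too short to exclude")
        if len(m) > length:
            raise ValueError(f"planted motif {m!r} longer than genome")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(list(_BASES), size=length, p=p)
    seq = "".join(arr)

    for rel, run_len in n_runs:
        start = int(rel * length)
        seq = seq[:start] + "N" * min(run_len, length - start) + seq[start + run_len :]

    both = strand_mode == "both"
    motifs = list(planted_absent_motifs)
    for _ in range(max_repair):
        hit = _find_hit(seq, motifs, both)
        if hit is None:
            return ContigSequence(id=contig_id, residues=seq)
        i, m_len = hit
        patch = "".join(rng.choice(list(_BASES), size=m_len, p=p))
        seq = seq[:i] + patch + seq[i + m_len :]
    raise RuntimeError("motif exclusion did not converge; motifs too dense/short")


def _random_cds(seq_piece: str, strand: str) -> bool:
    """True if the piece translates without internal stop on the given strand."""
    cds = seq_piece if strand == "+" else revcomp(seq_piece)
    if len(cds) % 3 != 0:
        return False
    aas = [CODON_TABLE.get(cds[i : i + 3], "X") for i in range(0, len(cds), 3)]
    return "*" not in aas and "X" not in aas


def synth_annotation(
    genome: ContigSequence,
    n_genes: int,
    seed: int = 0,
    max_tries: int = 500,
) -> list[GeneModel]:
    """Non-overlapping two-exon gene models on alternating strands, with a
    stop-free CDS inside the exons and UTRs on both sides."""
    rng = np.random.default_rng(seed)
    L = len(genome.residues)
    slot = L // n_genes
    if slot < 400:
        raise ValueError(f"genome too short to pack {n_genes} genes")
    models = []
    for gi in range(n_genes):
        strand = "+" if gi % 2 == 0 else "-"
        base = gi * slot
        placed = False
        for _ in range(max_tries):
            start = base + int(rng.integers(50, slot // 4))
            exon1_len = int(rng.integers(60, 120))
            intron_len = int(rng.integers(40, 100))
            exon2_len = int(rng.integers(60, 120))
            end = start + exon1_len + intron_len + exon2_len - 1
            if end >= base + slot - 10 or end > L:
                continue
            exon1 = (start, start + exon1_len - 1)
            exon2 = (end - exon2_len + 1, end)
            # CDS: tail of exon1 + head of exon2, total divisible by 3
            c1 = int(rng.integers(30, exon1_len - 15))
            c2 = int(rng.integers(30, exon2_len - 15))
            total = c1 + c2
            c2 -= total % 3
            if c2 < 3:
                continue
            cds1 = (exon1[1] - c1 + 1, exon1[1])
            cds2 = (exon2[0], exon2[0] + c2 - 1)
            spliced = (
                genome.residues[cds1[0] - 1 : cds1[1]]
                + genome.residues[cds2[0] - 1 : cds2[1]]
            )
            if not _random_cds(spliced, strand):
                continue
            tss, tes = (start, end) if strand == "+" else (end, start)
            cds_ivs = [cds1, cds2]
            utr_left = [(exon1[0], cds1[0] - 1)] if cds1[0] > exon1[0] else []
            utr_right = [(cds2[1] + 1, exon2[1])] if cds2[1] < exon2[1] else []
            utr5, utr3 = (utr_left, utr_right) if strand == "+" else (utr_right, utr_left)
            models.append(
                GeneModel(
                    transcript_id=f"tx{gi + 1}",
                    gene_id=f"gene{gi + 1}",
                    contig=genome.id,
                    strand=strand,
                    tss=tss,
                    tes=tes,
                    exons=[exon1, exon2],
                    cds=cds_ivs,
                    utr5=utr5,
                    utr3=utr3,
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place gene {gi + 1} without an internal stop")
    return models


def write_gff3(models: Iterable[GeneModel], path) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for gm in models:
            lo, hi = gm.span
            attrs = f"ID={gm.transcript_id};gene_id={gm.gene_id}"
            out.write(
                f"{gm.contig}\tnullkit\ttranscript\t{lo}\t{hi}\t.\t{gm.strand}\t.\t{attrs}\n"
            )
            for s, e in gm.exons:
                out.write(
                    f"{gm.contig}\tnullkit\texon\t{s}\t{e}\t.\t{gm.strand}\t.\tParent={gm.transcript_id};gene_id={gm.gene_id}\n"
                )
            for s, e in gm.cds:
                out.write(
                    f"{gm.contig}\tnullkit\tCDS\t{s}\t{e}\t.\t{gm.strand}\t0\tParent={gm.transcript_id};gene_id={gm.gene_id}\n"
                )


def synth_vcf(
    genome: ContigSequence,
    n_variants: int,
    populations: Sequence[str] = GNOMAD_POPULATIONS,
    seed: int = 0,
    engineered: Sequence[tuple] = (),
    beta: tuple = (0.5, 10.0),
) -> list[VariantRecord]:
    """Random SNVs and 1-bp indels with REF matching the genome.

    Allele frequencies (global and per population) are Beta(a, b) draws,
    emulating a many-rare / few-common site-frequency shape.
    ``engineered`` entries are explicit (pos, ref, alt[, af]) tuples
    appended verbatim (e.g. variants constructed to materialize chosen
    absent words).
    """
    rng = np.random.default_rng(seed)
    seq = genome.residues
    L = len(seq)
    records = []

    def afs():
        af = float(np.clip(rng.beta(*beta), 1e-6, 1.0))
        by_pop = {p: float(np.clip(rng.beta(*beta), 1e-6, 1.0)) for p in populations}
        return af, by_pop

    tries = 0
    while len(records) < n_variants and tries < 50 * n_variants:
        tries += 1
        pos = int(rng.integers(2, L))
        ref1 = seq[pos - 1]
        if ref1 not in _BASES:
            continue
        kind = rng.random()
        if kind < 0.6:  # SNV
            alt = _BASES[int(rng.integers(4))]
            if alt == ref1:
                continue
            ref, alt_out = ref1, alt
        elif kind < 0.8:  # 1-bp insertion (left-anchored)
            alt_out = ref1 + _BASES[int(rng.integers(4))]
            ref = ref1
        else:  # 1-bp deletion (anchored on previous base)
            prev = seq[pos - 2]
            if prev not in _BASES:
                continue
            pos -= 1
            ref, alt_out = prev + ref1, prev
        af, by_pop = afs()
        records.append(
            VariantRecord(
                contig=genome.id, pos=pos, ref=ref, alt=alt_out,
                af_global=af, af_by_population=by_pop,
            )
        )
    for entry in engineered:
        pos, ref, alt = entry[:3]
        af = entry[3] if len(entry) > 3 else 0.1
        if seq[pos - 1 : pos - 1 + len(ref)] != ref:
            raise ValueError(f"engineered variant REF mismatch at {pos}")
        _, by_pop = afs()
        records.append(
            VariantRecord(
                contig=genome.id, pos=pos, ref=ref, alt=alt,
                af_global=af, af_by_population=by_pop,
            )
        )
    records.sort(key=lambda v: (v.contig, v.pos))
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    genome: ContigSequence,
    path,
    populations: Sequence[str] = GNOMAD_POPULATIONS,
) -> None:
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##contig=<ID={genome.id},length={len(genome.residues)}>\n")
        out.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        for p in populations:
            out.write(
                f'##INFO=<ID=AF_{p},Number=A,Type=Float,Description="{p} allele frequency">\n'
            )
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in records:
            info = [f"AF={v.af_global:.6g}"]
            for p in populations:
                if p in v.af_by_population:
                    info.append(f"AF_{p}={v.af_by_population[p]:.6g}")
            out.write(
                f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{';'.join(info)}\n"
            )


def synth_proteome(
    n_proteins: int,
    length_range: tuple = (50, 200),
    seed: int = 0,
    planted_absent_motifs: Sequence[str] = (),
    max_repair: int = 10000,
) -> list[ContigSequence]:
    """Random proteins over the 20 standard amino acids, optionally with
    guaranteed-absent planted peptide motifs."""
    rng = np.random.default_rng(seed)
    letters = list(AA20.letters)
    proteins = []
    for i in range(n_proteins):
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(letters, size=n))
        for _ in range(max_repair):
            hit = None
            for m in planted_absent_motifs:
                j = seq.find(m)
                if j >= 0:
                    hit = (j, len(m))
                    break
            if hit is None:
                break
            j, m_len = hit
            seq = seq[:j] + "".join(rng.choice(letters, size=m_len)) + seq[j + m_len :]
        else:
            raise RuntimeError("peptide motif exclusion did not converge")
        proteins.append(ContigSequence(id=f"prot{i + 1}", residues=seq))
    return proteins


def synth_cds(
    n: int,
    n_codons_range: tuple = (20, 60),
    seed: int = 0,
) -> dict:
    """Random stop-free coding sequences keyed by transcript id."""
    rng = np.random.default_rng(seed)
    sense = [c for c, aa in CODON_TABLE.items() if aa != "*"]
    out = {}
    for i in range(n):
        n_codons = int(rng.integers(*n_codons_range))
        idx = rng.integers(0, len(sense), size=n_codons)
        out[f"tx{i + 1}"] = "".join(sense[j] for j in idx)
    return out


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def oracle_nullomers(
    sequences: Iterable,
    k: int,
    strand_mode: str = "both",
    alphabet: Alphabet = DNA4,
) -> set:
    """Naive absent-word enumeration: every window into a plain set, then
    the complement over the explicit word space.  Refuses |alphabet|^k
    beyond 10^6."""
    if alphabet.space(k) > 10**6:
        raise ValueError(f"oracle size guard exceeded: {alphabet.size}^{k} > 1e6")
    valid = set(alphabet.letters)
    observed = set()
    for seq in sequences:
        s = getattr(seq, "residues", seq)
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) <= valid:
                observed.add(w)
                if strand_mode == "both" and alphabet is DNA4:
                    observed.add(revcomp(w))
    return {
        "".join(t) for t in itertools.product(alphabet.letters, repeat=k)
    } - observed


def _present_words(seq: str, k: int, both: bool) -> set:
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" not in w:
            out.add(w)
            if both:
                out.add(revcomp(w))
    return out


def oracle_mutation_scan(
    genome: ContigSequence | str,
    k: int,
    strand_mode: str = "both",
) -> set:
    """Exhaustive mutate-and-rescan oracle for the materialization map.

    Applies every candidate single-base edit to the whole sequence,
    rescans fully, and diffs presence sets.  Returns a set of
    (mclass, pos, ref, alt, frozenset(words)) tuples.  Guards: genome
    <= 2000 bp, k <= 5.
    """
    seq = getattr(genome, "residues", genome)
    name = getattr(genome, "id", "seq")
    if len(seq) > 2000 or k > 5:
        raise ValueError("oracle size guard exceeded (genome <= 2000 bp, k <= 5)")
    both = strand_mode == "both"
    before = _present_words(seq, k, both)
    events = set()

    def check(mclass, pos, ref, alt, mutated):
        new = _present_words(mutated, k, both) - before
        if new:
            events.add((mclass, pos, ref, alt, frozenset(new)))

    L = len(seq)
    for pos in range(1, L + 1):
        ref = seq[pos - 1]
        if ref in _BASES:
            for alt in _BASES:
                if alt != ref:
                    check("SUB", pos, ref, alt, seq[: pos - 1] + alt + seq[pos:])
            check("DEL", pos, ref, "", seq[: pos - 1] + seq[pos:])
        for alt in _BASES:
            check("INS", pos, "", alt, seq[: pos - 1] + alt + seq[pos - 1 :])
    for alt in _BASES:
        check("INS", L + 1, "", alt, seq + alt)
    return events
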