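"""Sequence, annotation, region, and variant ingestion.

Coordinate conventions: GFF/GTF and VCF intervals are held 1-based
inclusive internally; BED input is converted from 0-based half-open at
the boundary.  All residues are uppercased on ingestion; DNA symbols
outside {A,C,G,T} map to N and nonstandard amino acids to X.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from ._alphabet import AA20, DNA4, Alphabet, revcomp

log = logging.getLogger(__name__)

__all__ = [
    "ContigSequence",
    "GeneModel",
    "CompartmentExtract",
    "VariantRecord",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "read_bed",
    "promoter_window",
    "extract_compartments",
    "read_vcf_records",
    "GNOMAD_POPULATIONS",
]

GNOMAD_POPULATIONS = ("afr", "ami", "amr", "asj", "eas", "fin", "nfe", "sas")

_DNA_VALID = set("ACGTN")
_AA_NONSTANDARD = set("BJOUXZ*")


@dataclass
class ContigSequence:
    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """One transcript with genomic-coordinate structure (1-based inclusive)."""

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    tss: int
    tes: int
    exons: list = field(default_factory=list)
    cds: list = field(default_factory=list)
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return min(self.tss, self.tes), max(self.tss, self.tes)


@dataclass
class CompartmentExtract:
    label: str
    sequences: list


@dataclass
class VariantRecord:
    contig: str
    pos: int
    ref: str
    alt: str
    af_global: float
    af_by_population: dict = field(default_factory=dict)

    @property
    def mclass(self) -> str:
        if len(self.ref) == len(self.alt):
            return "SUB"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"


def _normalize(residues: str, alphabet: Alphabet) -> str:
    residues = residues.upper()
    if alphabet is DNA4:
        return "".join(ch if ch in _DNA_VALID else "N" for ch in residues)
    return "".join(
        "X" if (ch in _AA_NONSTANDARD or ch not in AA20.letters) else ch for ch in residues
    )


def read_fasta(path, alphabet: Alphabet = DNA4) -> list[ContigSequence]:
    """Parse a FASTA file into normalized :class:`ContigSequence` records.

    Soft-masked (lowercase) residues are uppercased; DNA non-ACGTN symbols
    map to N; nonstandard protein symbols (B, J, O, U, X, Z, ``*``) map to X.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
        while first and not first.strip():
            first = handle.readline()
        if not first:
            raise ValueError(f"{path}: empty FASTA file (line 1)")
        if not first.startswith(">"):
            raise ValueError(f"{path}: malformed FASTA header at line 1: {first.strip()!r}")
    records = [
        ContigSequence(id=rec.id, residues=_normalize(str(rec.seq), alphabet))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    for rec in records:
        if len(rec.residues) < 1:
            raise ValueError(f"{path}: record {rec.id!r} has empty sequence")
    return records


def write_fasta(records: Iterable, path, width: int = 70) -> None:
    with open(path, "w") as out:
        for rec in records:
            rid = getattr(rec, "id", None) or rec[0]
            seq = getattr(rec, "residues", None) or rec[1]
            out.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# annotation parsing (GENCODE-dialect GTF / GFF3)
# ---------------------------------------------------------------------------


def _parse_attributes(raw: str, dialect: str) -> dict:
    attrs = {}
    if dialect == "gtf":
        for part in raw.strip().split(";"):
            part = part.strip()
            if not part:
                continue
            key, _, value = part.partition(" ")
            attrs[key] = value.strip().strip('"')
    else:
        for part in raw.strip().split(";"):
            part = part.strip()
            if not part:
                continue
            key, _, value = part.partition("=")
            attrs[key] = value
    return attrs


def _merge_intervals(intervals: list) -> list:
    merged = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _subtract_intervals(base: list, minus: list) -> list:
    """Interval set difference over 1-based inclusive intervals."""
    out = []
    minus = _merge_intervals(minus)
    for start, end in _merge_intervals(base):
        cur = start
        for ms, me in minus:
            if me < cur or ms > end:
                continue
            if ms > cur:
                out.append((cur, ms - 1))
            cur = max(cur, me + 1)
            if cur > end:
                break
        if cur <= end:
            out.append((cur, end))
    return out


def read_annotation(path, dialect: str = "gff3") -> list[GeneModel]:
    """Read transcripts from a GTF or GFF3 file into :class:`GeneModel` s.

    UTRs are derived from exon-minus-CDS set difference when not given
    explicitly.  Transcripts without exons are skipped with a warning.
    """
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    feats: dict[str, dict] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 columns, got {len(fields)}")
            contig, _, ftype, start, end, _, strand, _, raw = fields
            attrs = _parse_attributes(raw, dialect)
            if dialect == "gtf":
                tid = attrs.get("transcript_id")
                gid = attrs.get("gene_id", tid)
            else:
                if ftype in ("transcript", "mRNA"):
                    tid = attrs.get("ID")
                    gid = attrs.get("Parent", attrs.get("gene_id", tid))
                else:
                    tid = attrs.get("Parent")
                    gid = attrs.get("gene_id")
            if tid is None:
                continue
            entry = feats.setdefault(
                tid, {"gene_id": None, "contig": contig, "strand": strand,
                      "exons": [], "cds": [], "utr5": [], "utr3": [], "span": None}
            )
            if gid and not entry["gene_id"]:
                entry["gene_id"] = gid
            iv = (int(start), int(end))
            if ftype == "exon":
                entry["exons"].append(iv)
            elif ftype == "CDS":
                entry["cds"].append(iv)
            elif ftype in ("five_prime_UTR", "5UTR"):
                entry["utr5"].append(iv)
            elif ftype in ("three_prime_UTR", "3UTR"):
                entry["utr3"].append(iv)
            elif ftype in ("transcript", "mRNA"):
                entry["span"] = iv

    models = []
    for tid, entry in feats.items():
        exons = _merge_intervals(entry["exons"])
        if not exons:
            log.warning("transcript %s has no exons; skipped", tid)
            continue
        strand = entry["strand"]
        lo = min(s for s, _ in exons)
        hi = max(e for _, e in exons)
        if entry["span"]:
            lo, hi = min(lo, entry["span"][0]), max(hi, entry["span"][1])
        tss, tes = (lo, hi) if strand == "+" else (hi, lo)
        cds = _merge_intervals(entry["cds"])
        utr5, utr3 = entry["utr5"], entry["utr3"]
        if cds and not (utr5 or utr3):
            cds_lo = min(s for s, _ in cds)
            cds_hi = max(e for _, e in cds)
            noncoding = _subtract_intervals(exons, [(cds_lo, cds_hi)])
            left = [iv for iv in noncoding if iv[1] < cds_lo]
            right = [iv for iv in noncoding if iv[0] > cds_hi]
            utr5, utr3 = (left, right) if strand == "+" else (right, left)
        models.append(
            GeneModel(
                transcript_id=tid,
                gene_id=entry["gene_id"] or tid,
                contig=entry["contig"],
                strand=strand,
                tss=tss,
                tes=tes,
                exons=exons,
                cds=cds,
                utr5=_merge_intervals(utr5),
                utr3=_merge_intervals(utr3),
            )
        )
    return models


def read_bed(path) -> list[tuple]:
    """BED3+ regions as (contig, start, end), converted to 1-based inclusive."""
    out = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: BED needs >= 3 columns")
            out.append((fields[0], int(fields[1]) + 1, int(fields[2])))
    return out


def promoter_window(
    gene: GeneModel,
    upstream: int = 2500,
    downstream: int = 500,
    contig_length: int | None = None,
) -> tuple[int, int]:
    """Strand-aware promoter interval around the TSS, clipped to the contig."""
    if gene.strand == "+":
        lo, hi = gene.tss - upstream, gene.tss + downstream
    else:
        lo, hi = gene.tss - downstream, gene.tss + upstream
    lo = max(1, lo)
    if contig_length is not None:
        hi = min(hi, contig_length)
    return lo, hi


COMPARTMENT_LABELS = (
    "genome", "genic", "ccds", "exonic", "intronic", "utr5", "utr3", "promoter",
)

# spliced compartments: exon pieces concatenated in transcript order
_SPLICED = {"ccds": "cds", "exonic": "exons", "utr5": "utr5", "utr3": "utr3"}


def _spliced_sequence(seq: str, intervals: list, strand: str) -> str:
    pieces = "".join(seq[s - 1 : e] for s, e in sorted(intervals))
    return revcomp(pieces) if strand == "-" else pieces


def extract_compartments(
    genome: Sequence[ContigSequence],
    gene_models: Sequence[GeneModel],
    labels: Iterable[str] = COMPARTMENT_LABELS,
    promoter_upstream: int = 2500,
    promoter_downstream: int = 500,
) -> list[CompartmentExtract]:
    """Derive functional-compartment sequence sets from a genome.

    genic/promoter/intronic are genomic interval sequences; ccds/exonic/
    utr5/utr3 are spliced transcript-level sequences (reverse-complemented
    on the minus strand).  Identical sequences are deduplicated per label.
    """
    contigs = {c.id: c.residues for c in genome}
    labels = list(labels)
    unknown = set(labels) - set(COMPARTMENT_LABELS)
    if unknown:
        raise ValueError(f"unknown compartment labels: {sorted(unknown)}")
    by_label: dict[str, list] = {lab: [] for lab in labels}

    for gm in gene_models:
        if gm.contig not in contigs:
            raise KeyError(f"transcript {gm.transcript_id}: contig {gm.contig!r} not in genome")
        seq = contigs[gm.contig]
        lo, hi = gm.span
        if "genic" in by_label:
            by_label["genic"].append(seq[lo - 1 : hi])
        if "promoter" in by_label:
            plo, phi = promoter_window(
                gm, promoter_upstream, promoter_downstream, contig_length=len(seq)
            )
            by_label["promoter"].append(seq[plo - 1 : phi])
        if "intronic" in by_label:
            for s, e in _subtract_intervals([(lo, hi)], gm.exons):
                by_label["intronic"].append(seq[s - 1 : e])
        for label, attr in _SPLICED.items():
            if label in by_label:
                intervals = getattr(gm, attr)
                if intervals:
                    by_label[label].append(_spliced_sequence(seq, intervals, gm.strand))

    extracts = []
    for label in labels:
        if label == "genome":
            seqs = [c.residues for c in genome]
        else:
            seen, seqs = set(), []
            for s in by_label[label]:
                if s and s not in seen:
                    seen.add(s)
                    seqs.append(s)
        extracts.append(CompartmentExtract(label=label, sequences=seqs))
    return extracts


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _keep_allele(ref: str, alt: str) -> bool:
    """Retain SNVs and 1-bp net-length indels only."""
    if len(ref) == 1 and len(alt) == 1:
        return True
    return abs(len(ref) - len(alt)) == 1


def read_vcf_records(path, population_keys: Sequence[str] = GNOMAD_POPULATIONS) -> list[VariantRecord]:
    """Stream a VCF with gnomAD-style per-population AF INFO keys.

    Multi-allelic records are split; alleles other than SNVs / 1-bp indels
    are dropped; records lacking AF are dropped with a warning; a missing
    population AF is recorded as absent (not zero).
    """
    import pysam

    out = []
    n_no_af = 0
    def _info_get(rec, key):
        try:
            return rec.info.get(key)
        except (KeyError, ValueError):  # key not declared in the header
            return None

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vcf = pysam.VariantFile(str(path))
        for rec in vcf:
            alts = rec.alts or ()
            af = _info_get(rec, "AF")
            if af is None:
                n_no_af += 1
                continue
            if not isinstance(af, (tuple, list)):
                af = (af,) * len(alts)
            pop_afs = {}
            for pop in population_keys:
                val = _info_get(rec, f"AF_{pop}")
                if val is not None:
                    pop_afs[pop] = val if isinstance(val, (tuple, list)) else (val,) * len(alts)
            for i, alt in enumerate(alts):
                if alt is None or not _keep_allele(rec.ref, alt):
                    continue
                af_i = af[i] if i < len(af) else None
                if af_i is None:
                    n_no_af += 1
                    continue
                by_pop = {
                    pop: float(vals[i])
                    for pop, vals in pop_afs.items()
                    if i < len(vals) and vals[i] is not None
                }
                out.append(
                    VariantRecord(
                        contig=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        af_global=float(af_i),
                        af_by_population=by_pop,
                    )
                )
    if n_no_af:
        log.warning("%d VCF alleles dropped for missing AF", n_no_af)
    for v in out:
        if not 0.0 <= v.af_global <= 1.0:
            raise ValueError(f"AF out of [0,1] at {v.contig}:{v.pos}")
    return out
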