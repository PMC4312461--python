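"""Plain-text interchange: FASTA/FASTQ/SAM/VCF readers and writers.

Read identifiers encode provenance (source chromosome, origin interval,
strand) so that downstream stages run from files retain the truth-aware
ledger needed for damage profiling and evaluation:

    <serial>|c<chrom>|<origin_start>-<origin_end>|<strand>
"""

from __future__ import annotations

import numpy as np

from .align_call import CalledVariant, MappedRead, _fill_alignment_caches
from .read_sim import ReadRecord
from .seq import wrap_fasta

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "read_fastq",
    "read_sam",
    "read_calls_vcf",
    "read_truth_vcf",
]


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                seqs[name].append(line.upper())
    return {n: "".join(parts) for n, parts in seqs.items()}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{wrap_fasta(seq)}\n")


def _read_name(read: ReadRecord, serial: int) -> str:
    return (
        f"{serial}|c{read.source_chromosome}|"
        f"{read.origin_start}-{read.origin_end}|{read.strand}"
    )


def write_fastq(reads: list[ReadRecord], path) -> None:
    """Phred+33 FASTQ with provenance-encoding identifiers."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            qual = "".join(chr(int(q) + 33) for q in r.quality)
            fh.write(f"@{_read_name(r, i)}\n{r.sequence}\n+\n{qual}\n")


def read_fastq(path) -> list[ReadRecord]:
    reads: list[ReadRecord] = []
    with open(path) as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual_s = fh.readline().strip()
            rid = header[1:]
            try:
                _, chrom_s, span, strand = rid.split("|")
                chrom = int(chrom_s[1:])
                start, end = (int(x) for x in span.split("-"))
            except ValueError:
                chrom, start, end, strand = 1, 0, len(seq), "+"
            qual = np.frombuffer(qual_s.encode(), dtype=np.uint8) - 33
            reads.append(ReadRecord(rid, chrom, start, end, strand, seq, qual))
    return reads


def read_sam(path, reference: str) -> list[MappedRead]:
    """Rebuild MappedRead records from a SAM emitted by this pipeline."""
    out: list[MappedRead] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            flag = int(f[1])
            if flag & 4:
                continue
            strand = "-" if flag & 16 else "+"
            pos = int(f[3]) - 1
            cigar = []
            num = ""
            for ch in f[5]:
                if ch.isdigit():
                    num += ch
                else:
                    cigar.append((ch, int(num)))
                    num = ""
            seq = f[9]
            qual = np.frombuffer(f[10].encode(), dtype=np.uint8) - 33
            if strand == "-":
                qual = qual[::-1]
            nm = 0
            for tag in f[11:]:
                if tag.startswith("NM:i:"):
                    nm = int(tag[5:])
            read = ReadRecord(f[0], 1, 0, len(seq), strand, seq, qual)
            m = MappedRead(read, pos, strand, cigar, nm, int(f[4]), seq)
            _fill_alignment_caches(m, reference)
            out.append(m)
    return out


def _vcf_rows(path):
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            yield line.rstrip("\n").split("\t")


def read_calls_vcf(path) -> list[CalledVariant]:
    """Parse a calls VCF back into CalledVariant records (0-based)."""
    calls: list[CalledVariant] = []
    for f in _vcf_rows(path):
        pos1, ref_a, alt_a = int(f[1]), f[3], f[4].split(",")[0]
        qual = float(f[5]) if f[5] not in ".∅" else 0.0
        depth = 1
        for kv in f[7].split(";"):
            if kv.startswith("DP="):
                depth = int(kv[3:])
        gt = f[9].split(":")[0] if len(f) > 9 else "0/1"
        genotype = "hom" if gt in ("1/1", "1|1") else "het"
        if len(ref_a) == 1 and len(alt_a) == 1:
            calls.append(
                CalledVariant(pos1 - 1, "snp", ref_a, alt_a, genotype, qual, depth)
            )
        elif len(ref_a) > len(alt_a):
            calls.append(
                CalledVariant(
                    pos1, "deletion", ref_a[1:], "", genotype, qual, depth
                )
            )
        else:
            calls.append(
                CalledVariant(
                    pos1, "insertion", "", alt_a[1:], genotype, qual, depth
                )
            )
    return calls


def read_truth_vcf(path):
    """Parse a truth VCF into (snps, indels) evaluation events (0-based)."""
    from .evaluate import TruthEvent

    snps: list[TruthEvent] = []
    indels: list[TruthEvent] = []
    for f in _vcf_rows(path):
        pos1, ref_a = int(f[1]), f[3]
        alts = f[4].split(",")
        gt = f[9].split(":")[0] if len(f) > 9 else "0/1"
        if gt in ("1/1", "1|1"):
            copies_per_alt = [2]
        elif gt in ("1/2", "2/1"):
            copies_per_alt = [1, 1]
        else:
            copies_per_alt = [1] * len(alts)
        for alt_a, copies in zip(alts, copies_per_alt):
            if len(ref_a) == 1 and len(alt_a) == 1:
                snps.append(TruthEvent(pos1 - 1, "snp", alt_a, copies))
            elif len(ref_a) > len(alt_a):
                indels.append(TruthEvent(pos1, "deletion", ref_a[1:], copies))
            else:
                indels.append(TruthEvent(pos1, "insertion", alt_a[1:], copies))
    return snps, indels
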