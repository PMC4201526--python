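"""miRNA reference bundle: precursors, mature arms, families, contaminants.

The bundle mirrors the objects a miRBase release provides for annotation:
precursor (hairpin) loci with genomic coordinates, the 5p/3p mature arms with
a star (passenger-strand) designation, seed-based family membership, and an
optional set of labelled contaminant references (rRNA/tRNA/snRNA/snoRNA/srpRNA)
used to categorise non-miRNA reads.

Serialisation uses the conventional file shapes: mature and hairpin FASTA, a
miRBase-dialect GFF3 (``miRNA_primary_transcript`` and ``miRNA`` features with
``ID``/``Name``/``Derives_from`` attributes, 1-based inclusive coordinates) and
a family TSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CONTAMINANT_ORDER = ("rRNA", "tRNA", "snRNA", "snoRNA", "srpRNA")

_VALID_SEQ = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class Precursor:
    """A miRNA primary transcript locus (1-based inclusive coordinates)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    sequence: str | None = None  # hairpin sequence, if known

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"precursor {self.id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"precursor {self.id}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class Arm:
    """A mature miRNA arm (5p or 3p product of one precursor)."""

    id: str
    precursor_id: str
    arm: str  # "5p" or "3p"
    sequence: str
    star: bool = False

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm {self.id}: arm label must be 5p or 3p, got {self.arm!r}")
        if not _VALID_SEQ.match(self.sequence):
            raise ValueError(f"arm {self.id}: sequence must be A/C/G/T only")
        if not (18 <= len(self.sequence) <= 30):
            raise ValueError(
                f"arm {self.id}: sequence length {len(self.sequence)} outside 18-30 nt"
            )


@dataclass
class ReferenceBundle:
    """Annotation universe for quantification and genomic-context analysis."""

    precursors: dict[str, Precursor] = field(default_factory=dict)
    arms: dict[str, Arm] = field(default_factory=dict)
    families: dict[str, list[str]] = field(default_factory=dict)  # family -> arm ids
    contaminants: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def validate(self) -> None:
        for arm in self.arms.values():
            if arm.precursor_id not in self.precursors:
                raise ValueError(f"arm {arm.id} references unknown precursor {arm.precursor_id}")
        for pre_id in self.precursors:
            labels = [a.arm for a in self.arms.values() if a.precursor_id == pre_id]
            if labels.count("5p") > 1 or labels.count("3p") > 1:
                raise ValueError(f"precursor {pre_id} has duplicate arm labels")
        for fam, members in self.families.items():
            unknown = [m for m in members if m not in self.arms]
            if unknown:
                raise ValueError(f"family {fam} lists unknown arms: {unknown}")
        for cat in self.contaminants:
            if cat not in CONTAMINANT_ORDER:
                raise ValueError(f"unknown contaminant category {cat!r}")

    def arms_of(self, precursor_id: str) -> list[Arm]:
        return [a for a in self.arms.values() if a.precursor_id == precursor_id]

    # ------------------------------------------------------------------ I/O

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write mature/hairpin FASTA, GFF3, family TSV and contaminant FASTA.

        Returns a mapping of logical name to written path. Output is
        deterministic: records are emitted in sorted-id order.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mature": outdir / "mature.fa",
            "hairpin": outdir / "hairpin.fa",
            "gff3": outdir / "annotation.gff3",
            "families": outdir / "families.tsv",
            "contaminants": outdir / "contaminants.fa",
        }

        mature = [
            SeqRecord(
                Seq(a.sequence),
                id=a.id,
                description=f"precursor={a.precursor_id} arm={a.arm} star={int(a.star)}",
            )
            for a in sorted(self.arms.values(), key=lambda a: a.id)
        ]
        SeqIO.write(mature, paths["mature"], "fasta")

        hairpins = [
            SeqRecord(Seq(p.sequence), id=p.id, description="")
            for p in sorted(self.precursors.values(), key=lambda p: p.id)
            if p.sequence
        ]
        SeqIO.write(hairpins, paths["hairpin"], "fasta")

        with open(paths["gff3"], "w") as fh:
            fh.write("##gff-version 3\n")
            for p in sorted(self.precursors.values(), key=lambda p: (p.chrom, p.start, p.id)):
                fh.write(
                    f"{p.chrom}\t.\tmiRNA_primary_transcript\t{p.start}\t{p.end}\t.\t"
                    f"{p.strand}\t.\tID={p.id};Name={p.id}\n"
                )
                for a in sorted(self.arms_of(p.id), key=lambda a: a.arm):
                    # synthetic arm placement: 5p at the precursor 5' end, 3p at the 3' end
                    if a.arm == "5p":
                        start, end = p.start, p.start + len(a.sequence) - 1
                    else:
                        start, end = p.end - len(a.sequence) + 1, p.end
                    fh.write(
                        f"{p.chrom}\t.\tmiRNA\t{start}\t{end}\t.\t{p.strand}\t.\t"
                        f"ID={a.id};Name={a.id};Derives_from={p.id}\n"
                    )

        with open(paths["families"], "w") as fh:
            fh.write("family\tarm_id\n")
            for fam in sorted(self.families):
                for arm_id in self.families[fam]:
                    fh.write(f"{fam}\t{arm_id}\n")

        contaminant_records = []
        for cat in CONTAMINANT_ORDER:
            for name, seq in self.contaminants.get(cat, []):
                contaminant_records.append(
                    SeqRecord(Seq(seq), id=name, description=f"category={cat}")
                )
        SeqIO.write(contaminant_records, paths["contaminants"], "fasta")
        return paths

    @classmethod
    def load(cls, indir: str | Path) -> "ReferenceBundle":
        indir = Path(indir)
        bundle = cls()

        hairpin_path = indir / "hairpin.fa"
        hairpin_seqs = {}
        if hairpin_path.exists():
            hairpin_seqs = {r.id: str(r.seq) for r in SeqIO.parse(hairpin_path, "fasta")}

        db = gffutils.create_db(
            str(indir / "annotation.gff3"),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="error",
        )
        for feat in db.features_of_type("miRNA_primary_transcript"):
            pid = feat.attributes["ID"][0]
            bundle.precursors[pid] = Precursor(
                id=pid,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                sequence=hairpin_seqs.get(pid),
            )

        arm_meta = {}
        for rec in SeqIO.parse(indir / "mature.fa", "fasta"):
            fields = dict(kv.split("=") for kv in rec.description.split()[1:])
            arm_meta[rec.id] = (str(rec.seq), fields)

        for feat in db.features_of_type("miRNA"):
            aid = feat.attributes["ID"][0]
            seq, fields = arm_meta[aid]
            bundle.arms[aid] = Arm(
                id=aid,
                precursor_id=feat.attributes["Derives_from"][0],
                arm=fields["arm"],
                sequence=seq,
                star=bool(int(fields.get("star", "0"))),
            )

        fam_path = indir / "families.tsv"
        if fam_path.exists():
            with open(fam_path) as fh:
                next(fh)  # header
                for line in fh:
                    fam, arm_id = line.rstrip("\n").split("\t")
                    bundle.families.setdefault(fam, []).append(arm_id)

        cont_path = indir / "contaminants.fa"
        if cont_path.exists():
            for rec in SeqIO.parse(cont_path, "fasta"):
                fields = dict(kv.split("=") for kv in rec.description.split()[1:])
                bundle.contaminants.setdefault(fields["category"], []).append(
                    (rec.id, str(rec.seq))
                )

        bundle.validate()
        return bundle
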