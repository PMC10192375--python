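"""Germline V/D/J/C segment database with CDR3 anchor bookkeeping.

A T cell receptor chain is assembled somatically from germline segments.  The
CDR3 (junction) region is delimited by two conserved residues: a cysteine near
the 3' end of every V gene and the phenylalanine/tryptophan of the F/W-G-X-G
motif in every J gene.  This module loads segment sequences together with the
0-based coordinate of the first base of that anchor codon, validates the
anchors, and provides the codon-translation utility used throughout the
package.

Coordinates are 0-based and half-open everywhere; ``anchor_offset`` points at
the first base of the anchor codon.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import GermlineError
from .util import validate_dna

CHAINS = ("alpha", "beta")
SEGMENT_TYPES = ("V", "D", "J", "C", "leader")

#: Amino acids accepted at the V (Cys) and J (Phe/Trp) anchors.
V_ANCHOR_AA = frozenset("C")
J_ANCHOR_AA = frozenset("FW")


def translate(nt: str, frame: int = 0) -> str:
    """Translate ``nt`` from reading-frame offset ``frame`` (0/1/2).

    Complete codons only; a trailing incomplete codon is dropped; stop codons
    are rendered as ``*``.  Raises on non-ACGT characters.
    """
    if frame not in (0, 1, 2):
        raise GermlineError(f"frame must be 0, 1 or 2, got {frame!r}")
    s = validate_dna(nt, what="translation input")
    trimmed = s[frame:]
    trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
    return str(Seq(trimmed).translate())


@dataclass(frozen=True)
class GermlineSegment:
    """One germline gene segment.

    ``anchor_offset`` is required for V and J segments (Cys codon for V,
    F/W codon of the F/W-G-X-G motif for J) and must be ``None`` otherwise.
    ``frame_offset`` is the reading-frame phase of the sequence start.
    """

    gene_name: str
    chain: str
    segment_type: str
    nt_sequence: str
    anchor_offset: int | None = None
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise GermlineError(f"{self.gene_name}: unknown chain {self.chain!r}")
        if self.segment_type not in SEGMENT_TYPES:
            raise GermlineError(
                f"{self.gene_name}: unknown segment type {self.segment_type!r}"
            )
        object.__setattr__(
            self, "nt_sequence", validate_dna(self.nt_sequence, what=self.gene_name)
        )
        if not self.nt_sequence:
            raise GermlineError(f"{self.gene_name}: empty sequence")
        if self.frame_offset not in (0, 1, 2):
            raise GermlineError(f"{self.gene_name}: bad frame_offset")
        if self.segment_type in ("V", "J"):
            if self.anchor_offset is None:
                raise GermlineError(f"{self.gene_name}: V/J segment needs an anchor")
            if not 0 <= self.anchor_offset <= len(self.nt_sequence) - 3:
                raise GermlineError(
                    f"{self.gene_name}: anchor_offset {self.anchor_offset} outside "
                    f"sequence of length {len(self.nt_sequence)}"
                )
            aa = translate(self.anchor_codon)
            expected = V_ANCHOR_AA if self.segment_type == "V" else J_ANCHOR_AA
            if aa not in expected:
                raise GermlineError(
                    f"{self.gene_name}: anchor codon {self.anchor_codon} encodes "
                    f"{aa!r}, expected one of {sorted(expected)}"
                )
        elif self.anchor_offset is not None:
            raise GermlineError(
                f"{self.gene_name}: anchor_offset only valid for V/J segments"
            )

    @property
    def anchor_codon(self) -> str:
        assert self.anchor_offset is not None
        return self.nt_sequence[self.anchor_offset : self.anchor_offset + 3]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.chain, self.segment_type, self.gene_name)


@dataclass
class GermlineDB:
    """Collection of :class:`GermlineSegment` keyed by (chain, type, name)."""

    segments: dict[tuple[str, str, str], GermlineSegment] = field(default_factory=dict)
    version_tag: str = ""

    def add(self, seg: GermlineSegment) -> None:
        if seg.key in self.segments:
            raise GermlineError(f"duplicate segment key {seg.key}")
        self.segments[seg.key] = seg

    def get(self, chain: str, segment_type: str, gene_name: str) -> GermlineSegment:
        try:
            return self.segments[(chain, segment_type, gene_name)]
        except KeyError:
            raise GermlineError(
                f"no {chain} {segment_type} segment named {gene_name!r}"
            ) from None

    def of_type(self, chain: str, segment_type: str) -> list[GermlineSegment]:
        """All segments of one chain/type, sorted by gene name."""
        out = [
            s
            for (c, t, _), s in self.segments.items()
            if c == chain and t == segment_type
        ]
        return sorted(out, key=lambda s: s.gene_name)

    def validate(self) -> None:
        for chain in CHAINS:
            for st in ("V", "J"):
                if not self.of_type(chain, st):
                    raise GermlineError(f"database lacks any {chain} {st} segment")

    def __len__(self) -> int:
        return len(self.segments)

    def write(self, fasta_path: str | Path, anchors_path: str | Path) -> None:
        """Write the database as FASTA + anchor TSV (the loader's format)."""
        records = []
        rows = []
        for seg in sorted(self.segments.values(), key=lambda s: s.key):
            records.append(
                SeqRecord(Seq(seg.nt_sequence), id=seg.gene_name, description="")
            )
            rows.append(
                {
                    "gene_name": seg.gene_name,
                    "chain": seg.chain,
                    "segment_type": seg.segment_type,
                    "anchor_offset": "" if seg.anchor_offset is None else seg.anchor_offset,
                    "frame_offset": seg.frame_offset,
                }
            )
        SeqIO.write(records, str(fasta_path), "fasta")
        with open(anchors_path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh,
                fieldnames=["gene_name", "chain", "segment_type", "anchor_offset", "frame_offset"],
                delimiter="\t",
            )
            writer.writeheader()
            writer.writerows(rows)


def load_germline(
    fasta_path: str | Path,
    anchors_path: str | Path,
    *,
    version_tag: str = "",
    collapse_alleles: bool = False,
) -> GermlineDB:
    """Load a germline database from FASTA + anchor table.

    The anchor table is tab-separated with header columns ``gene_name``,
    ``chain``, ``segment_type``, ``anchor_offset`` (empty for D/C/leader) and
    ``frame_offset``.  Every FASTA record must have a matching anchor row;
    V/J anchors are validated on load (Cys for V, Phe/Trp for J).

    With ``collapse_alleles=True``, allele suffixes (``*01``) are stripped
    from gene names; the first-seen allele of each gene is kept.
    """
    meta: dict[str, dict[str, str]] = {}
    with open(anchors_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_name", "chain", "segment_type", "anchor_offset", "frame_offset"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise GermlineError(
                f"anchor table {anchors_path} must have columns {sorted(required)}"
            )
        for row in reader:
            meta[row["gene_name"]] = row

    db = GermlineDB(version_tag=version_tag or Path(fasta_path).stem)
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        name = rec.id
        if name not in meta:
            raise GermlineError(f"FASTA record {name!r} has no anchor-table row")
        row = meta[name]
        if collapse_alleles and "*" in name:
            name = name.split("*")[0]
            if any(k[2] == name for k in db.segments):
                continue  # keep first allele seen
        anchor = row["anchor_offset"].strip()
        seg = GermlineSegment(
            gene_name=name,
            chain=row["chain"],
            segment_type=row["segment_type"],
            nt_sequence=str(rec.seq),
            anchor_offset=int(anchor) if anchor else None,
            frame_offset=int(row["frame_offset"]),
        )
        db.add(seg)
    db.validate()
    return db


def bundled_germline() -> GermlineDB:
    """The synthetic IMGT-like germline fixture shipped with the package."""
    data = resources.files("tcrscreen") / "data"
    return load_germline(
        str(data / "germline_synthetic.fasta"),
        str(data / "germline_synthetic_anchors.tsv"),
        version_tag="tcrscreen-synthetic-1",
    )
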