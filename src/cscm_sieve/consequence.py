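"""Coding-consequence annotation against simple gene models.

Classifies SNVs and small indels (missense / synonymous / stop gained or
lost / frameshift / in-frame indel), maps genomic to CDS coordinates across
spliced, stranded transcripts, and emits HGVS-like g. / c. / p. labels such
as ``p.Gly20Trp`` or ``p.Ser3592fs``.

The labels are deliberately "HGVS-like": duplications are recognised when a
single inserted base equals the base it follows, but full HGVS
3'-normalisation and its edge cases are out of scope.  For indels the
reported first-affected codon is the arithmetic frame-shift start
``ceil((p + 1) / 3)`` for an edit anchored after CDS position p — the codon
where the reading frame changes, which for coincidental sequence matches may
precede the first residue that actually differs after translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio.Data.IUPACData import protein_letters_1to3
from Bio.Seq import Seq

from .core import VariantRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

CONSEQUENCE_CLASSES = (
    "synonymous",
    "missense",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift",
    "inframe_indel",
    "splice_site",
    "non_coding",
)

#: classes the variant-prioritization filters treat as protein-changing
PROTEIN_CHANGING = frozenset(
    {"missense", "stop_gained", "stop_lost", "start_lost", "frameshift", "inframe_indel", "splice_site"}
)


def _aa3(aa: str) -> str:
    """One-letter amino acid (or '*') to the three-letter HGVS form."""
    return "Ter" if aa == "*" else protein_letters_1to3[aa]


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model with its coding sequence.

    ``cds_segments`` are genomic 1-based inclusive intervals in ascending
    genomic order; for minus-strand genes the transcript walks them from the
    last segment's ``end`` down to the first segment's ``start``.
    ``cds_seq`` is the strand-corrected coding sequence, 5'->3'.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    cds_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        segs = self.cds_segments
        if not segs:
            raise ValueError("gene model needs at least one CDS segment")
        for (s, e) in segs:
            if e < s or s < 1:
                raise ValueError(f"bad CDS segment ({s}, {e})")
        for (_, e0), (s1, _) in zip(segs, segs[1:]):
            if s1 <= e0:
                raise ValueError("CDS segments overlap or are unordered")
        if sum(e - s + 1 for s, e in segs) != len(self.cds_seq):
            raise ValueError("cds_seq length inconsistent with CDS segments")

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)

    @property
    def span(self) -> tuple[int, int]:
        return (self.cds_segments[0][0], self.cds_segments[-1][1])

    def contains(self, pos: int) -> bool:
        return self.span[0] <= pos <= self.span[1]


@dataclass(frozen=True)
class ConsequenceCall:
    variant: VariantRecord
    transcript: str
    consequence: str
    cds_pos: int | None = None
    codon: int | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    c_label: str | None = None
    p_label: str | None = None
    passthrough: Mapping[str, str] = field(default_factory=dict, compare=False)

    @property
    def is_protein_changing(self) -> bool:
        return self.consequence in PROTEIN_CHANGING

    @property
    def g_label(self) -> str:
        return self.variant.g_label


def codon_index(cds_pos: int) -> int:
    """1-based codon index of a CDS position: ceil(cds_pos / 3)."""
    if cds_pos < 1:
        raise ValueError("cds_pos must be >= 1")
    return (cds_pos + 2) // 3


def map_genomic_to_cds(model: GeneModel, pos: int) -> int | None:
    """Map a genomic position to its 1-based CDS coordinate.

    Walks the CDS segments in transcript order, accumulating offsets;
    strand-aware.  Returns None for intronic positions (or positions outside
    the transcript span).
    """
    segments = model.cds_segments if model.strand == "+" else model.cds_segments[::-1]
    offset = 0
    for s, e in segments:
        if s <= pos <= e:
            return offset + (pos - s + 1 if model.strand == "+" else e - pos + 1)
        offset += e - s + 1
    return None


def map_cds_to_genomic(model: GeneModel, cds_pos: int) -> int:
    """Inverse of :func:`map_genomic_to_cds` over CDS positions."""
    if not 1 <= cds_pos <= model.cds_length:
        raise ValueError(f"cds_pos {cds_pos} outside CDS of length {model.cds_length}")
    segments = model.cds_segments if model.strand == "+" else model.cds_segments[::-1]
    offset = 0
    for s, e in segments:
        width = e - s + 1
        if cds_pos <= offset + width:
            within = cds_pos - offset
            return s + within - 1 if model.strand == "+" else e - within + 1
        offset += width
    raise AssertionError("unreachable")


def _tx_allele(model: GeneModel, allele: str) -> str:
    return allele if model.strand == "+" else allele.translate(_COMPLEMENT)[::-1]


def _check_ref(model: GeneModel, cds_pos: int, ref_tx: str) -> None:
    have = model.cds_seq[cds_pos - 1 : cds_pos - 1 + len(ref_tx)]
    if have != ref_tx:
        raise ValueError(
            f"{model.gene_id}: reference allele {ref_tx!r} does not match model "
            f"sequence {have!r} at CDS position {cds_pos}"
        )


def annotate_snv(model: GeneModel, variant: VariantRecord) -> ConsequenceCall:
    """Annotate a single-nucleotide substitution against one gene model."""
    if not variant.is_snv:
        raise ValueError("annotate_snv requires a SNV")
    cds_pos = map_genomic_to_cds(model, variant.pos)
    if cds_pos is None:
        return ConsequenceCall(variant, model.transcript_id, "non_coding")
    ref_tx = _tx_allele(model, variant.ref)
    alt_tx = _tx_allele(model, variant.alt)
    _check_ref(model, cds_pos, ref_tx)
    ci = codon_index(cds_pos)
    codon_start = (ci - 1) * 3
    ref_codon = model.cds_seq[codon_start : codon_start + 3]
    within = cds_pos - 1 - codon_start
    alt_codon = ref_codon[:within] + alt_tx + ref_codon[within + 1 :]
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        cls = "synonymous"
    elif ci == 1 and aa_ref == "M":
        cls = "start_lost"
    elif aa_alt == "*":
        cls = "stop_gained"
    elif aa_ref == "*":
        cls = "stop_lost"
    else:
        cls = "missense"
    c_label = f"c.{cds_pos}{ref_tx}>{alt_tx}"
    p_label = f"p.{_aa3(aa_ref)}{ci}{_aa3(aa_alt)}"
    return ConsequenceCall(
        variant, model.transcript_id, cls, cds_pos, ci, aa_ref, aa_alt, c_label, p_label
    )


def _indel_in_cds_space(model: GeneModel, variant: VariantRecord) -> tuple[int, str, str] | None:
    """Express a VCF-anchored indel as a CDS-space edit.

    Returns (anchor_cds_pos, inserted_seq, deleted_seq): the edit applies
    immediately after CDS position ``anchor``.  None when the edit does not
    lie wholly inside the CDS (caller classifies as splice-site placeholder
    or non-coding).
    """
    ref, alt = variant.ref, variant.alt
    if len(ref) == 1 and len(alt) > 1 and alt[0] == ref:  # insertion
        inserted = alt[1:]
        if model.strand == "+":
            anchor = map_genomic_to_cds(model, variant.pos)
            if anchor is None:
                return None
            return anchor, inserted, ""
        # minus strand: the insertion between genomic pos and pos+1 sits
        # between cds(pos+1) and cds(pos); anchor at the transcript-earlier one
        nxt = map_genomic_to_cds(model, variant.pos + 1)
        here = map_genomic_to_cds(model, variant.pos)
        if nxt is None or here is None:
            return None
        return nxt, _tx_allele(model, inserted), ""
    if len(alt) == 1 and len(ref) > 1 and ref[0] == alt:  # deletion
        del_first, del_last = variant.pos + 1, variant.pos + len(ref) - 1
        if model.strand == "+":
            anchor = map_genomic_to_cds(model, variant.pos)
            a = map_genomic_to_cds(model, del_first)
            b = map_genomic_to_cds(model, del_last)
            if anchor is None or a is None or b is None or b - a != del_last - del_first:
                return None
            return anchor, "", _tx_allele(model, variant.ref[1:])
        a = map_genomic_to_cds(model, del_last)  # transcript-first deleted base
        b = map_genomic_to_cds(model, del_first)
        if a is None or b is None or b - a != del_last - del_first:
            return None
        return a - 1, "", _tx_allele(model, variant.ref[1:])
    raise ValueError("indel must be VCF-anchored (ref and alt share the first base)")


def annotate_indel(model: GeneModel, variant: VariantRecord) -> ConsequenceCall:
    """Annotate a VCF-anchored insertion or deletion against one gene model.

    Frameshift when the net length change is not a multiple of 3, else
    in-frame; first affected codon ceil((anchor + 1) / 3).  Edits spanning a
    CDS/intron boundary are classed as the splice-site placeholder.
    """
    if variant.is_snv:
        raise ValueError("annotate_indel requires an insertion or deletion")
    if map_genomic_to_cds(model, variant.pos) is None and not (
        model.contains(variant.pos) or model.contains(variant.pos + len(variant.ref) - 1)
    ):
        return ConsequenceCall(variant, model.transcript_id, "non_coding")
    edit = _indel_in_cds_space(model, variant)
    if edit is None:
        return ConsequenceCall(variant, model.transcript_id, "splice_site")
    anchor, inserted, deleted = edit
    if deleted:
        _check_ref(model, anchor + 1, deleted)
    net = len(inserted) - len(deleted)
    ci = codon_index(anchor + 1)
    aa_ref = str(Seq(model.cds_seq[(ci - 1) * 3 : ci * 3]).translate()) if ci * 3 <= model.cds_length else None
    if net % 3 != 0:
        cls = "frameshift"
        p_label = f"p.{_aa3(aa_ref)}{ci}fs" if aa_ref else f"p.{ci}fs"
    else:
        cls = "inframe_indel"
        p_label = None
    if inserted and not deleted:
        dup = len(inserted) == 1 and model.cds_seq[anchor - 1] == inserted
        c_label = f"c.{anchor}dup{inserted}" if dup else f"c.{anchor}_{anchor + 1}ins{inserted}"
    elif deleted and not inserted:
        first, last = anchor + 1, anchor + len(deleted)
        c_label = f"c.{first}del" if first == last else f"c.{first}_{last}del"
    else:
        c_label = f"c.{anchor}delins{inserted}"
    return ConsequenceCall(
        variant, model.transcript_id, cls, anchor + 1, ci, aa_ref, None, c_label, p_label
    )


def annotate(models: list[GeneModel], variant: VariantRecord) -> ConsequenceCall:
    """Annotate a variant against the first gene model whose span contains it.

    Variants outside every model are non-coding.  (Single-transcript models;
    multi-transcript ranking is out of scope.)
    """
    last = variant.pos + len(variant.ref) - 1
    for model in models:
        if model.chrom == variant.chrom and (model.contains(variant.pos) or model.contains(last)):
            return annotate_snv(model, variant) if variant.is_snv else annotate_indel(model, variant)
    return ConsequenceCall(variant, "", "non_coding")


def mutate_and_translate(model: GeneModel, anchor: int, inserted: str, deleted: str) -> str:
    """Apply a CDS-space edit and translate the mutated sequence.

    Used as the independent re-translation cross-check for the indel codon
    arithmetic: translation stops at the first stop codon of the mutated
    frame; the trailing partial codon of a shifted frame is dropped.
    """
    seq = model.cds_seq[:anchor] + inserted + model.cds_seq[anchor + len(deleted) :]
    seq = seq[: len(seq) - len(seq) % 3]
    return str(Seq(seq).translate(to_stop=True))


# ---------------------------------------------------------------------------
# gene-model I/O


def read_gene_models_tsv(path: str | Path) -> list[GeneModel]:
    """Read gene models from the flat TSV dialect.

    Columns: gene_id, transcript_id, chrom, strand, cds_segments
    ("start-end,start-end", ascending genomic), cds_seq.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    models = []
    for row in df.itertuples(index=False):
        segs = tuple(
            tuple(int(x) for x in part.split("-")) for part in row.cds_segments.split(",")
        )
        models.append(
            GeneModel(row.gene_id, row.transcript_id, row.chrom, row.strand, segs, row.cds_seq)
        )
    return models


def write_gene_models_tsv(models: list[GeneModel], path: str | Path) -> Path:
    rows = [
        {
            "gene_id": m.gene_id,
            "transcript_id": m.transcript_id,
            "chrom": m.chrom,
            "strand": m.strand,
            "cds_segments": ",".join(f"{s}-{e}" for s, e in m.cds_segments),
            "cds_seq": m.cds_seq,
        }
        for m in models
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_gene_models_gff3(gff_path: str | Path, fasta_path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 CDS features plus a reference FASTA."""
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    fasta = Fasta(str(fasta_path))
    models = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            continue
        segs = tuple((f.start, f.end) for f in cds)
        strand = mrna.strand
        pieces = [str(fasta[mrna.seqid][s - 1 : e]) for s, e in segs]
        seq = "".join(pieces).upper()
        if strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        models.append(GeneModel(gene_id, mrna.id, mrna.seqid, strand, segs, seq))
    return models
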