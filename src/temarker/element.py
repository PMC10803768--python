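"""Element-integrity annotation and insertion-site excision.

A genuine cut-and-paste transposition leaves two diagnostic scars: a
duplicated target-site motif (TTAA for piggyBac-family elements)
immediately flanking the element, and reverse-complementary inverted
terminal repeats (ITRs) at the element's own termini. This module detects
both, classifies the transposase reading frame (intact / frameshifted /
premature stop), and excises the element to reconstruct the pre-insertion
locus: 5' flank + one copy of the duplication + 3' flank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Seq import Seq

from .align import MutationCatalog, apply_catalog
from .io import StrainMeta

CANONICAL_TSD = "TTAA"

ITR_MIN_LEN = 13       # piggyBac terminal repeats are 13 bp
ITR_MAX_MISMATCH = 1
ORF_SPAN = (329, 2113)  # transposase reading frame, 1-based reference coords


@dataclass
class ElementRecord:
    """One strain's element in its genomic context.

    ``element_span`` is the 0-based half-open slice of ``full_seq``
    containing the element itself (TSD copies excluded).
    """

    strain: StrainMeta
    full_seq: str
    element_span: tuple[int, int]
    tsd_status: str = "unknown"   # canonical_TTAA | other_duplication | absent
    tsd: str | None = None
    itr5: str = ""
    itr3: str = ""
    itr_intact: bool = False
    orf_status: str = "not_found"  # intact | frameshifted | premature_stop | not_found

    @property
    def element_seq(self) -> str:
        s, e = self.element_span
        return self.full_seq[s:e]

    @property
    def flank5(self) -> str:
        return self.full_seq[: self.element_span[0] - 4]

    @property
    def flank3(self) -> str:
        return self.full_seq[self.element_span[1] + 4 :]


@dataclass
class FlankPair:
    """The reconstructed pre-insertion locus."""

    flank5: str
    flank3: str
    tsd: str

    @property
    def concatenated(self) -> str:
        return self.flank5 + self.tsd + self.flank3


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def detect_tsd(full_seq: str, element_span: tuple[int, int]) -> str:
    """Classify the 4-mers immediately flanking the element.

    canonical_TTAA if both equal TTAA; other_duplication if equal but not
    TTAA; absent otherwise.
    """
    s, e = element_span
    if s < 4 or e + 4 > len(full_seq):
        raise ValueError("element span leaves fewer than 4 nt of flank on one side")
    left, right = full_seq[s - 4 : s], full_seq[e : e + 4]
    if left == right == CANONICAL_TSD:
        return "canonical_TTAA"
    if left == right:
        return "other_duplication"
    return "absent"


def detect_itrs(element_seq: str, min_len: int = ITR_MIN_LEN,
                max_mismatch: int = ITR_MAX_MISMATCH) -> tuple[str, str, bool]:
    """Find the longest terminal inverted repeat of the element.

    Returns (5' repeat, 3' repeat, intact) where the repeat is the longest
    prefix whose reverse complement matches the suffix of the same length
    with at most ``max_mismatch`` mismatches, and intact means its length
    reaches ``min_len``.
    """
    n = len(element_seq)
    if n < 2 * min_len:
        return "", "", False
    prefix = np.frombuffer(element_seq.encode(), dtype="S1")
    rc = np.frombuffer(revcomp(element_seq).encode(), dtype="S1")
    best = 0
    # revcomp(element)[:L] is the reverse complement of the last L bases
    for L in range(1, n // 2 + 1):
        if int((prefix[:L] != rc[:L]).sum()) <= max_mismatch:
            best = L
    if best == 0:
        return "", "", False
    return element_seq[:best], element_seq[n - best :], best >= min_len


def orf_check(reference: str, catalog: MutationCatalog,
              ref_orf_span: tuple[int, int] = ORF_SPAN) -> str:
    """Classify the transposase reading frame of a decayed element.

    Frameshifted if, within the ORF span, the net indel length is not a
    multiple of 3 or any single indel has length not a multiple of 3;
    otherwise the mutated ORF is translated and classified as
    premature_stop or intact. Span is 1-based inclusive reference coords.
    """
    start, end = ref_orf_span
    if not (1 <= start <= end <= len(reference)):
        raise ValueError(f"ORF span {ref_orf_span} outside reference of length {len(reference)}")
    catalog.validate()
    net = 0
    for dstart, dlen in catalog.deletions:
        dend = dstart + dlen - 1
        if dstart <= end and dend >= start:
            inside = min(dend, end) - max(dstart, start) + 1
            if inside % 3 != 0:
                return "frameshifted"
            net -= inside
    for pos, ins in catalog.insertions:
        if start <= pos < end:  # insertion strictly inside the span
            if len(ins) % 3 != 0:
                return "frameshifted"
            net += len(ins)
    if net % 3 != 0:
        return "frameshifted"
    # rebuild the mutated ORF region and translate it
    sub = MutationCatalog(
        ref_length=end - start + 1,
        substitutions=[(p - start + 1, r, a) for p, r, a in catalog.substitutions
                       if start <= p <= end],
        deletions=[(max(ds, start) - start + 1, min(ds + dl - 1, end) - max(ds, start) + 1)
                   for ds, dl in catalog.deletions if ds <= end and ds + dl - 1 >= start],
        insertions=[(p - start + 1, s) for p, s in catalog.insertions if start <= p < end],
    )
    orf_nt = apply_catalog(reference[start - 1 : end], sub)
    orf_nt = orf_nt[: len(orf_nt) - len(orf_nt) % 3]
    aa = str(Seq(orf_nt).translate())
    if "*" in aa[:-1]:
        return "premature_stop"
    return "intact"


def excise_and_concat(rec: ElementRecord) -> FlankPair:
    """Delete the element plus one TSD copy and join the genomic flanks."""
    if rec.tsd_status not in ("canonical_TTAA", "other_duplication"):
        raise ValueError(
            f"strain {rec.strain.strain_id}: no duplicated target site at the element "
            "boundaries; review the element span manually before excising"
        )
    s, e = rec.element_span
    tsd = rec.full_seq[s - 4 : s]
    return FlankPair(flank5=rec.full_seq[: s - 4], flank3=rec.full_seq[e + 4 :], tsd=tsd)


def locate_element(full_seq: str, reference_element: str,
                   scoring: dict | None = None) -> tuple[int, int]:
    """Locate the element within a genomic fragment by semi-global alignment.

    The reference element is aligned end-to-end against ``full_seq`` with
    free end gaps on the genomic side; the aligned footprint (0-based,
    half-open) is returned.
    """
    from .align import DEFAULT_SCORING

    s = dict(DEFAULT_SCORING)
    if scoring:
        s.update(scoring)
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = s["match"]
    a.mismatch_score = s["mismatch"]
    a.open_gap_score = s["gap_open"]
    a.extend_gap_score = s["gap_extend"]
    a.end_deletion_score = 0.0  # unaligned genomic flanks are free
    aln = a.align(full_seq, reference_element)[0]
    blocks = aln.aligned[0]
    return int(blocks[0][0]), int(blocks[-1][1])


def annotate(strain: StrainMeta, full_seq: str, reference_element: str,
             catalog: MutationCatalog | None = None,
             itr_min_len: int = ITR_MIN_LEN, itr_max_mismatch: int = ITR_MAX_MISMATCH,
             orf_span: tuple[int, int] = ORF_SPAN,
             scoring: dict | None = None) -> ElementRecord:
    """Full integrity annotation of one strain's element-plus-flank sequence."""
    from .align import extract_catalog, global_align

    span = locate_element(full_seq, reference_element, scoring=scoring)
    rec = ElementRecord(strain=strain, full_seq=full_seq, element_span=span)
    rec.tsd_status = detect_tsd(full_seq, span)
    if rec.tsd_status != "absent":
        rec.tsd = full_seq[span[0] - 4 : span[0]]
    rec.itr5, rec.itr3, rec.itr_intact = detect_itrs(
        rec.element_seq, min_len=itr_min_len, max_mismatch=itr_max_mismatch
    )
    if catalog is None:
        catalog = extract_catalog(global_align(reference_element, rec.element_seq,
                                               scoring=scoring))
    rec.orf_status = orf_check(reference_element, catalog, ref_orf_span=orf_span)
    return rec
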