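"""Pairwise global alignment, percent identity, and mutation catalogues.

A decayed element is summarised relative to its functional ancestor as a
``MutationCatalog``: substitutions, deletions and insertions in 1-based
reference coordinates. Catalogues are exact — applying one to the reference
reconstructs the descendant sequence byte-for-byte — which makes them both
the unit of comparison between strains ("shared signatures") and the ground
truth emitted by the decay simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .io import SequenceSet

DEFAULT_SCORING = {"match": 5.0, "mismatch": -4.0, "gap_open": -10.0, "gap_extend": -0.5}


@dataclass
class PairwiseAlignment:
    """Gapped rows of a global pairwise alignment plus its affine-gap score.

    A gap of length L costs ``gap_open + gap_extend * (L - 1)``.
    """

    ref_row: str
    qry_row: str
    score: float

    def __post_init__(self) -> None:
        if len(self.ref_row) != len(self.qry_row):
            raise ValueError("alignment rows differ in length")
        if any(a == "-" and b == "-" for a, b in zip(self.ref_row, self.qry_row)):
            raise ValueError("all-gap column in alignment")

    @property
    def ref(self) -> str:
        return self.ref_row.replace("-", "")

    @property
    def qry(self) -> str:
        return self.qry_row.replace("-", "")


@dataclass
class MutationCatalog:
    """Mutations of one sequence relative to a reference, 1-based coordinates.

    substitutions: (ref_pos, ref_base, alt_base)
    deletions:     (ref_start, length) — removes ref_start..ref_start+length-1
    insertions:    (ref_pos_before, inserted_string) — inserted after that
                   reference position (0 = before the first base)

    Events are sorted by position and non-overlapping.
    """

    ref_length: int
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    deletions: list[tuple[int, int]] = field(default_factory=list)
    insertions: list[tuple[int, str]] = field(default_factory=list)

    def validate(self) -> None:
        deleted: set[int] = set()
        for start, length in self.deletions:
            if length < 1 or start < 1 or start + length - 1 > self.ref_length:
                raise ValueError(f"deletion ({start},{length}) outside reference")
            run = set(range(start, start + length))
            if run & deleted:
                raise ValueError(f"overlapping deletions at {start}")
            deleted |= run
        for pos, ref_base, alt in self.substitutions:
            if not 1 <= pos <= self.ref_length:
                raise ValueError(f"substitution position {pos} outside reference")
            if pos in deleted:
                raise ValueError(f"substitution at deleted position {pos}")
            if ref_base == alt:
                raise ValueError(f"null substitution at {pos}")
        if len({p for p, _, _ in self.substitutions}) != len(self.substitutions):
            raise ValueError("duplicate substitution positions")
        for pos, ins in self.insertions:
            if not 0 <= pos <= self.ref_length:
                raise ValueError(f"insertion anchor {pos} outside reference")
            if not ins:
                raise ValueError(f"empty insertion at {pos}")
        if len({p for p, _ in self.insertions}) != len(self.insertions):
            raise ValueError("duplicate insertion anchors")

    def sort(self) -> None:
        self.substitutions.sort()
        self.deletions.sort()
        self.insertions.sort()

    @property
    def n_substituted(self) -> int:
        return len(self.substitutions)

    @property
    def n_deleted(self) -> int:
        return sum(length for _, length in self.deletions)

    @property
    def n_inserted(self) -> int:
        return sum(len(s) for _, s in self.insertions)

    def event_keys(self) -> set[tuple]:
        """Hashable identity of every event, for signature-sharing queries."""
        keys: set[tuple] = set()
        keys |= {("sub", p, alt) for p, _, alt in self.substitutions}
        keys |= {("del", s, length) for s, length in self.deletions}
        keys |= {("ins", p, s) for p, s in self.insertions}
        return keys


def apply_catalog(reference: str, catalog: MutationCatalog) -> str:
    """Reconstruct the descendant sequence from reference + catalogue."""
    if len(reference) != catalog.ref_length:
        raise ValueError("reference length does not match catalogue")
    catalog.validate()
    deleted: set[int] = set()
    for start, length in catalog.deletions:
        deleted |= set(range(start, start + length))
    subs = {p: alt for p, _, alt in catalog.substitutions}
    ins = dict(catalog.insertions)
    out: list[str] = [ins.get(0, "")]
    for pos in range(1, catalog.ref_length + 1):
        if pos not in deleted:
            out.append(subs.get(pos, reference[pos - 1]))
        out.append(ins.get(pos, ""))
    return "".join(out)


def _aligner(scoring: dict | None) -> Align.PairwiseAligner:
    s = dict(DEFAULT_SCORING)
    if scoring:
        s.update(scoring)
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = s["match"]
    a.mismatch_score = s["mismatch"]
    a.open_gap_score = s["gap_open"]
    a.extend_gap_score = s["gap_extend"]
    return a


def global_align(ref: str, qry: str, scoring: dict | None = None) -> PairwiseAlignment:
    """Optimal Needleman–Wunsch global alignment with affine gap costs.

    Ties are broken by the aligner's canonical traceback order, so the
    returned alignment is reproducible byte-for-byte.
    """
    if not ref or not qry:
        raise ValueError("cannot align an empty sequence")
    if "-" in ref or "-" in qry:
        raise ValueError("inputs to global_align must be ungapped")
    aln = _aligner(scoring).align(ref, qry)[0]
    return PairwiseAlignment(ref_row=str(aln[0]), qry_row=str(aln[1]), score=float(aln.score))


def percent_identity(a_row: str, b_row: str, count_gaps: bool = False) -> float:
    """Percent identity between two equal-length gapped rows.

    Default is gap-excluded (matches over columns where neither row is
    gapped), the convention of Clustal Omega's percent-identity matrix;
    ``count_gaps=True`` divides by all columns where at least one row has
    a residue instead.
    """
    if len(a_row) != len(b_row):
        raise ValueError("rows differ in length")
    a = np.frombuffer(a_row.encode(), dtype="S1")
    b = np.frombuffer(b_row.encode(), dtype="S1")
    both = (a != b"-") & (b != b"-")
    matches = int(((a == b) & both).sum())
    denom = int((both if not count_gaps else ((a != b"-") | (b != b"-"))).sum())
    if denom == 0:
        raise ValueError("no comparable columns between rows")
    return 100.0 * matches / denom


def identity_matrix(msa: SequenceSet, count_gaps: bool = False) -> pd.DataFrame:
    """All-pairs percent identity of an alignment, as a labeled square table."""
    if len(msa) < 2:
        raise ValueError("identity matrix needs at least 2 rows")
    ids = msa.ids
    n = len(ids)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(msa.entries[i][1], msa.entries[j][1], count_gaps=count_gaps)
            mat[i, j] = mat[j, i] = pid
    return pd.DataFrame(mat, index=ids, columns=ids)


def extract_catalog(aln: PairwiseAlignment) -> MutationCatalog:
    """Catalogue a pairwise alignment: maximal gap runs become single indels,
    mismatching gap-free columns become substitutions."""
    cat = MutationCatalog(ref_length=len(aln.ref))
    ref_pos = 0  # last consumed 1-based reference position
    i = 0
    n = len(aln.ref_row)
    while i < n:
        r, q = aln.ref_row[i], aln.qry_row[i]
        if r == "-":  # insertion run relative to reference
            j = i
            while j < n and aln.ref_row[j] == "-":
                j += 1
            cat.insertions.append((ref_pos, aln.qry_row[i:j]))
            i = j
        elif q == "-":  # deletion run
            j = i
            while j < n and aln.qry_row[j] == "-":
                j += 1
            cat.deletions.append((ref_pos + 1, j - i))
            ref_pos += j - i
            i = j
        else:
            ref_pos += 1
            if r != q:
                cat.substitutions.append((ref_pos, r, q))
            i += 1
    cat.sort()
    cat.validate()
    return cat


def catalog_identity(cat: MutationCatalog, count_gaps: bool = False) -> float:
    """Percent identity implied by a catalogue (equals the alignment-row value)."""
    compared = cat.ref_length - cat.n_deleted
    matches = compared - cat.n_substituted
    denom = compared if not count_gaps else cat.ref_length + cat.n_inserted
    if denom == 0:
        raise ValueError("no comparable columns")
    return 100.0 * matches / denom


def shared_signature(catalogs: dict[str, MutationCatalog]) -> pd.DataFrame:
    """Tabulate which strains carry each reference-relative mutation event.

    All catalogues must be against the same reference (checked via length).
    Rows are sorted by reference position; an event is shared by exactly the
    strains whose catalogues contain an identical event.
    """
    if not catalogs:
        raise ValueError("no catalogues given")
    lengths = {c.ref_length for c in catalogs.values()}
    if len(lengths) > 1:
        raise ValueError(f"catalogues built against different references: lengths {sorted(lengths)}")
    carriers: dict[tuple, list[str]] = {}
    for strain, cat in catalogs.items():
        for key in cat.event_keys():
            carriers.setdefault(key, []).append(strain)
    rows = []
    for (etype, pos, payload), strains in carriers.items():
        rows.append(
            {
                "type": etype,
                "ref_pos": pos,
                "detail": payload,
                "n_strains": len(strains),
                "strains": ",".join(sorted(strains)),
            }
        )
    df = pd.DataFrame(rows, columns=["type", "ref_pos", "detail", "n_strains", "strains"])
    return df.sort_values(["ref_pos", "type", "detail"], kind="stable").reset_index(drop=True)


def reference_pivot_msa(reference_id: str, reference: str,
                        catalogs: dict[str, MutationCatalog]) -> SequenceSet:
    """Stack pairwise catalogues into a pseudo-MSA on reference coordinates.

    Each strain row has one column per reference position (deletions as
    gaps, substitutions applied); insertions relative to the reference are
    dropped. This is a reference-pivoted projection, not a progressive
    multiple alignment, and downstream output is flagged as such.
    """
    entries = [(reference_id, reference)]
    for strain, cat in catalogs.items():
        if cat.ref_length != len(reference):
            raise ValueError(f"catalogue for {strain} does not match reference length")
        row = list(reference)
        for pos, _, alt in cat.substitutions:
            row[pos - 1] = alt
        for start, length in cat.deletions:
            for p in range(start, start + length):
                row[p - 1] = "-"
        entries.append((strain, "".join(row)))
    return SequenceSet(entries=entries, aligned=True)


def catalog_table(catalogs: dict[str, MutationCatalog]) -> pd.DataFrame:
    """Flat per-event TSV-ready table of all catalogues."""
    rows = []
    for strain in sorted(catalogs):
        cat = catalogs[strain]
        for pos, ref_base, alt in cat.substitutions:
            rows.append({"strain": strain, "type": "sub", "ref_pos": pos,
                         "length": 1, "detail": f"{ref_base}>{alt}"})
        for start, length in cat.deletions:
            rows.append({"strain": strain, "type": "del", "ref_pos": start,
                         "length": length, "detail": ""})
        for pos, ins in cat.insertions:
            rows.append({"strain": strain, "type": "ins", "ref_pos": pos,
                         "length": len(ins), "detail": ins})
    df = pd.DataFrame(rows, columns=["strain", "type", "ref_pos", "length", "detail"])
    return df.sort_values(["strain", "ref_pos", "type"], kind="stable").reset_index(drop=True)
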