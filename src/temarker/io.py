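"""Readers and writers for the external formats the pipeline touches.

No science lives here: FASTA / aligned FASTA / Clustal alignments, Newick
trees, the strain-metadata TSV and the flat key=value run configuration.

Coordinate convention: every reference coordinate reported to users (TSV
output, error messages, the transposase ORF span) is 1-based inclusive.
Internally sequences are ordinary Python strings indexed from 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd
from Bio import AlignIO, SeqIO

ALPHABET = set("ACGTN-")


@dataclass(frozen=True)
class StrainMeta:
    """One screened strain: a short unique id plus free-text provenance."""

    strain_id: str
    species_label: str = ""
    locale: str = ""
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.strain_id or any(c.isspace() for c in self.strain_id):
            raise ValueError(f"strain_id must be non-empty and whitespace-free: {self.strain_id!r}")


@dataclass
class SequenceSet:
    """Ordered, id-unique collection of nucleotide sequences.

    ``aligned`` sets have equal-length rows that may contain ``-``;
    unaligned sets must be gap-free.
    """

    entries: list[tuple[str, str]] = field(default_factory=list)
    aligned: bool = False

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sid, seq in self.entries:
            if sid in seen:
                raise ValueError(f"duplicate sequence id: {sid!r}")
            seen.add(sid)
            bad = set(seq) - ALPHABET
            if bad:
                raise ValueError(f"illegal characters {sorted(bad)} in sequence {sid!r}")
            if not self.aligned and "-" in seq:
                raise ValueError(f"gap character in unaligned sequence {sid!r}")
        if self.aligned and len({len(s) for _, s in self.entries}) > 1:
            lens = {sid: len(s) for sid, s in self.entries}
            raise ValueError(f"aligned set has ragged rows: {lens}")

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, sid: str) -> str:
        for s, seq in self.entries:
            if s == sid:
                return seq
        raise KeyError(sid)

    def as_dict(self) -> dict[str, str]:
        return dict(self.entries)


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> SequenceSet:
    """Read an unaligned FASTA file; uppercases and maps U→T.

    Duplicate ids and empty files are hard errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    entries = [(r.id, _normalize(str(r.seq))) for r in records]
    return SequenceSet(entries=entries, aligned=False)


def read_alignment(path: str | Path, dialect: str = "afa") -> SequenceSet:
    """Read a multiple alignment in aligned-FASTA (``afa``) or ``clustal`` format."""
    fmt = {"afa": "fasta", "clustal": "clustal"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown alignment dialect {dialect!r}; expected 'afa' or 'clustal'")
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        records = list(AlignIO.read(str(path), "clustal"))
    if not records:
        raise ValueError(f"no alignment rows in {path}")
    entries = [(r.id, _normalize(str(r.seq))) for r in records]
    return SequenceSet(entries=entries, aligned=True)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.entries:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as Newick; internal-node labels carry bootstrap support."""
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree has an unlabeled leaf")
    Path(path).write_text(newick_string(tree))


def newick_string(tree: dendropy.Tree) -> str:
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return s.strip() + "\n"


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def read_metadata(path: str | Path) -> list[StrainMeta]:
    """Strain metadata TSV with header strain_id/species_label/locale/accession."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"strain_id", "species_label", "locale"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata TSV missing columns: {sorted(missing)}")
    metas = [
        StrainMeta(
            strain_id=row["strain_id"],
            species_label=row["species_label"],
            locale=row["locale"],
            accession=row.get("accession") or None,
        )
        for _, row in df.iterrows()
    ]
    ids = [m.strain_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain_id in metadata")
    return metas


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, digits: int = 4) -> None:
    df.round(digits).to_csv(path, sep="\t", index_label="id")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# -- run configuration ---------------------------------------------------

CONFIG_KEYS = {
    "seed": int,
    "nu": float,
    "nu_ci_low": float,
    "nu_ci_high": float,
    "generation_days": float,
    "element_id_min": float,
    "flank_id_min": float,
    "signature_frac_min": float,
    "match": float,
    "mismatch": float,
    "gap_open": float,
    "gap_extend": float,
    "itr_min_len": int,
    "itr_max_mismatch": int,
    "orf_start": int,
    "orf_end": int,
    "bootstrap_reps": int,
    "distance_model": str,
    "lineage_split": str,
    "reference": str,
    "elements": str,
    "metadata": str,
    "alignment": str,
    "outdir": str,
}


def read_config(path: str | Path) -> dict:
    """Parse a flat ``key = value`` config file; unknown keys are hard errors."""
    cfg: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = (p.strip() for p in line.partition("="))
        if key not in CONFIG_KEYS:
            raise ValueError(
                f"{path}:{lineno}: unknown config key {key!r}; "
                f"valid keys: {', '.join(sorted(CONFIG_KEYS))}"
            )
        cfg[key] = CONFIG_KEYS[key](value)
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    lines = [f"{k} = {v}" for k, v in sorted(cfg.items())]
    Path(path).write_text("\n".join(lines) + "\n")
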