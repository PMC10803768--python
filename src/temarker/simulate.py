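"""Synthetic decay of a single transposon insertion along a strain tree.

The generator emulates the life history the pipeline is built to read out:
a functional element inserts once into a genomic locus at a TTAA site
(duplicating it), loses mobility, and then accumulates substitutions and
indels neutrally along the strain phylogeny. Mutations on shared branches
appear in every descendant — these are the "shared signatures" the
conspecificity caller keys on — while terminal branches contribute private
events. Ground truth (per-strain mutation catalogue, true tree, true
divergence in generations) is emitted alongside the sequences, so every
downstream stage can be tested against what actually happened.

Flanking genomic DNA evolves by substitution only, at a configurable
fraction of the element rate (default 1/10): the element lineages may far
predate the sampled strains' genomic coalescence, and the duplicated TTAA
itself is held fixed so target-site detection stays well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .align import MutationCatalog, apply_catalog, catalog_table
from .io import SequenceSet, write_config, write_fasta, write_newick

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_TRANSVERSION = str.maketrans("ACGT", "CATG")

DEFAULT_SUB_RATE = 5.8e-9      # per site per generation (= 0.0058 / Myr-gen)
DEFAULT_INDEL_RATE = 3e-10     # per site per generation
DEFAULT_ELEMENT_LEN = 2472
DEFAULT_ORF_SPAN = (329, 2113)


@dataclass
class DecayParams:
    """Everything the decay simulator needs; deterministic given ``seed``."""

    ancestral_element: str | None = None      # random element if None
    strain_tree: dendropy.Tree | None = None  # branch lengths in generations
    sub_rate: float = DEFAULT_SUB_RATE
    indel_rate: float = DEFAULT_INDEL_RATE
    indel_len_geometric_p: float = 0.5
    heavy_tail: bool = False                  # admix long uniform indels
    flank_rate_fraction: float = 0.1          # flank rate = fraction * sub_rate
    flank_len5: int = 427
    flank_len3: int = 371
    element_len: int = DEFAULT_ELEMENT_LEN
    itr_len: int = 13
    orf_span: tuple[int, int] = DEFAULT_ORF_SPAN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sub_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0 < self.indel_len_geometric_p <= 1:
            raise ValueError("indel_len_geometric_p must be in (0, 1]")
        if self.flank_len5 < 4 or self.flank_len3 < 4:
            raise ValueError("flanks must be at least 4 nt")


@dataclass
class DecayTruth:
    """Simulator ground truth for recovery tests."""

    catalogs: dict[str, MutationCatalog]
    tree: dendropy.Tree
    divergence_generations: dict[str, float]
    ancestral_element: str
    flank5: str
    flank3: str
    warnings: list[str] = field(default_factory=list)


class _Lineage:
    """Mutation state of one lineage relative to the ancestral element."""

    __slots__ = ("subs", "deleted", "ins", "f5", "f3")

    def __init__(self) -> None:
        self.subs: dict[int, str] = {}
        self.deleted: set[int] = set()
        self.ins: dict[int, str] = {}
        self.f5: dict[int, str] = {}
        self.f3: dict[int, str] = {}

    def copy(self) -> "_Lineage":
        c = _Lineage()
        c.subs = dict(self.subs)
        c.deleted = set(self.deleted)
        c.ins = dict(self.ins)
        c.f5 = dict(self.f5)
        c.f3 = dict(self.f3)
        return c


def random_element(length: int = DEFAULT_ELEMENT_LEN, itr_len: int = 13,
                   orf_span: tuple[int, int] = DEFAULT_ORF_SPAN,
                   rng: np.random.Generator | None = None) -> str:
    """Random ancestral element with planted inverted terminal repeats and an
    open (stop-free) reading frame across ``orf_span`` when it fits."""
    rng = rng or np.random.default_rng(0)
    seq = list(rng.choice(list(_BASES), size=length))
    start, end = orf_span
    if end <= length and (end - start + 1) % 3 == 0:
        i = start - 1
        while i + 3 <= end:
            while "".join(seq[i : i + 3]) in _STOPS:
                seq[i : i + 3] = rng.choice(list(_BASES), size=3)
            i += 3
    if itr_len and length >= 2 * itr_len:
        motif = seq[:itr_len]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        seq[length - itr_len :] = [comp[b] for b in reversed(motif)]
    return "".join(seq)


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _draw_indel_len(rng: np.random.Generator, params: DecayParams) -> int:
    if params.heavy_tail and rng.random() < 0.15:
        return int(rng.integers(5, 51))
    return int(rng.geometric(params.indel_len_geometric_p))


def _mutate_flank(flank: str, subs: dict[int, str], rate: float, t: float,
                  rng: np.random.Generator) -> None:
    n = rng.poisson(rate * t * len(flank))
    for _ in range(n):
        pos = int(rng.integers(1, len(flank) + 1))
        cur = subs.get(pos, flank[pos - 1])
        new = str(rng.choice([b for b in _BASES if b != cur]))
        if new == flank[pos - 1]:
            subs.pop(pos, None)
        else:
            subs[pos] = new


def _evolve_element(state: _Lineage, element: str, t: float,
                    params: DecayParams, rng: np.random.Generator) -> None:
    L = len(element)
    surviving = sorted(set(range(1, L + 1)) - state.deleted)
    if not surviving:
        return
    n_sub = rng.poisson(params.sub_rate * t * len(surviving))
    for _ in range(n_sub):
        pos = int(rng.choice(surviving))
        cur = state.subs.get(pos, element[pos - 1])
        new = str(rng.choice([b for b in _BASES if b != cur]))
        if new == element[pos - 1]:
            state.subs.pop(pos, None)  # back-mutation restores the reference
        else:
            state.subs[pos] = new
    n_indel = rng.poisson(params.indel_rate * t * len(surviving))
    for _ in range(n_indel):
        length = _draw_indel_len(rng, params)
        if rng.random() < 0.5:  # deletion of the next `length` surviving sites
            i = int(rng.integers(0, len(surviving)))
            run = surviving[i : i + length]
            state.deleted.update(run)
            for p in run:
                state.subs.pop(p, None)
            surviving = [p for p in surviving if p not in state.deleted]
            # re-anchor insertions whose anchor was deleted to the nearest
            # surviving position on the left (events stay non-overlapping)
            for anchor in [a for a in state.ins if a in state.deleted]:
                left = max((p for p in surviving if p < anchor), default=0)
                moved = state.ins.pop(anchor)
                state.ins[left] = state.ins.get(left, "") + moved
            if not surviving:
                return
        else:
            anchor = int(rng.choice([0] + surviving))
            state.ins[anchor] = state.ins.get(anchor, "") + _random_seq(length, rng)


def _state_to_catalog(state: _Lineage, element: str) -> MutationCatalog:
    deletions: list[tuple[int, int]] = []
    run_start = None
    prev = None
    for p in sorted(state.deleted):
        if run_start is None:
            run_start, prev = p, p
        elif p == prev + 1:
            prev = p
        else:
            deletions.append((run_start, prev - run_start + 1))
            run_start, prev = p, p
    if run_start is not None:
        deletions.append((run_start, prev - run_start + 1))
    cat = MutationCatalog(
        ref_length=len(element),
        substitutions=sorted((p, element[p - 1], a) for p, a in state.subs.items()),
        deletions=deletions,
        insertions=sorted(state.ins.items()),
    )
    cat.validate()
    return cat


def _apply_subs(seq: str, subs: dict[int, str]) -> str:
    if not subs:
        return seq
    out = list(seq)
    for pos, alt in subs.items():
        out[pos - 1] = alt
    return "".join(out)


def simulate_decay(params: DecayParams) -> tuple[SequenceSet, DecayTruth]:
    """Decay the ancestral element along the strain tree.

    Returns the per-strain full sequences (5' flank + TTAA + decayed
    element + TTAA + 3' flank) and the ground truth. Mutations accumulated
    on shared branches are inherited by every descendant strain.
    """
    rng = np.random.default_rng(params.seed)
    element = params.ancestral_element or random_element(
        params.element_len, itr_len=params.itr_len, orf_span=params.orf_span, rng=rng
    )
    tree = params.strain_tree
    if tree is None:
        tree = balanced_tree(["S1", "S2", "S3", "S4"], tip_len=1e6, internal_len=2e6)
    warnings: list[str] = []
    if len(element) < 2 * params.itr_len:
        warnings.append(f"element shorter than twice the ITR minimum ({params.itr_len})")
    flank5 = _random_seq(params.flank_len5, rng)
    flank3 = _random_seq(params.flank_len3, rng)
    flank_rate = params.flank_rate_fraction * params.sub_rate

    states: dict[int, _Lineage] = {id(tree.seed_node): _Lineage()}
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    entries: list[tuple[str, str]] = []
    catalogs: dict[str, MutationCatalog] = {}
    divergence: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = float(node.edge.length or 0.0)
        state = states[id(node.parent_node)].copy()
        _evolve_element(state, element, t, params, rng)
        _mutate_flank(flank5, state.f5, flank_rate, t, rng)
        _mutate_flank(flank3, state.f3, flank_rate, t, rng)
        states[id(node)] = state
        depth[id(node)] = depth[id(node.parent_node)] + t
        if node.is_leaf():
            strain = node.taxon.label
            cat = _state_to_catalog(state, element)
            catalogs[strain] = cat
            divergence[strain] = depth[id(node)]
            full = (
                _apply_subs(flank5, state.f5)
                + "TTAA"
                + apply_catalog(element, cat)
                + "TTAA"
                + _apply_subs(flank3, state.f3)
            )
            entries.append((strain, full))
    truth = DecayTruth(
        catalogs=catalogs,
        tree=tree,
        divergence_generations=divergence,
        ancestral_element=element,
        flank5=flank5,
        flank3=flank3,
        warnings=warnings,
    )
    return SequenceSet(entries=entries, aligned=False), truth


# -- canned trees and fixtures --------------------------------------------

def balanced_tree(labels: list[str], tip_len: float, internal_len: float) -> dendropy.Tree:
    """Two balanced clades over ``labels`` (split in half), lengths in generations."""
    half = len(labels) // 2
    left = ",".join(f"{l}:{tip_len:.0f}" for l in labels[:half])
    right = ",".join(f"{l}:{tip_len:.0f}" for l in labels[half:])
    newick = f"(({left}):{internal_len:.0f},({right}):{internal_len:.0f});"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def two_clade_tree(n_a: int, n_b: int, stem_a: float, stem_b: float,
                   tip_len: float, prefix_a: str = "cladeA_",
                   prefix_b: str = "cladeB_") -> dendropy.Tree:
    """Star-within-clades topology: root splits into two stems with
    ``n_a`` and ``n_b`` tips; lengths in generations."""
    a = ",".join(f"{prefix_a}{i + 1:02d}:{tip_len:.0f}" for i in range(n_a))
    b = ",".join(f"{prefix_b}{i + 1:02d}:{tip_len:.0f}" for i in range(n_b))
    newick = f"(({a}):{stem_a:.0f},({b}):{stem_b:.0f});"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def saturated_pair(length: int = 300, fraction: float = 0.9,
                   seed: int = 0) -> SequenceSet:
    """A deterministic sequence pair past the TN93 invertible range:
    transversions applied to ``fraction`` of sites (designed error path)."""
    rng = np.random.default_rng(seed)
    ref = _random_seq(length, rng)
    n_hit = int(round(fraction * length))
    hit = set(rng.choice(length, size=n_hit, replace=False).tolist())
    mut = "".join(c.translate(_TRANSVERSION) if i in hit else c for i, c in enumerate(ref))
    return SequenceSet(entries=[("ancestor", ref), ("saturated", mut)], aligned=False)


FIXTURES = ("tiny", "paperlike", "saturated")


def fixture_params(name: str, seed: int = 0) -> DecayParams:
    """Preset simulation conditions for the named fixture."""
    if name == "tiny":
        return DecayParams(
            element_len=200, flank_len5=60, flank_len3=60,
            strain_tree=balanced_tree(["T1", "T2", "T3", "T4"],
                                      tip_len=1e6, internal_len=2e6),
            indel_rate=1e-9, orf_span=(31, 150), seed=seed,
        )
    if name == "paperlike":
        # Two element lineages: a shallow 10-strain clade and a deeper
        # 3-strain clade, with root-to-tip depths giving ~94-96% identity
        # to the ancestor and ~97% between clades, >99.6% within clades.
        return DecayParams(
            element_len=2472, flank_len5=427, flank_len3=371,
            strain_tree=two_clade_tree(10, 3, stem_a=3.85e6, stem_b=1.25e6,
                                       tip_len=5e4),
            seed=seed,
        )
    raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURES}")


def _paperlike_shared_root(tree: dendropy.Tree, shared: float = 5.6e6) -> dendropy.Tree:
    """Prefix the whole strain tree with one shared root branch."""
    new_root = dendropy.Node()
    old = tree.seed_node
    new_root.add_child(old)
    old.edge.length = shared
    tree.seed_node = new_root
    return tree


def make_fixture(name: str, outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a named fixture to ``outdir``: FASTA, truth TSV, Newick, config.

    tiny      — 4 strains x 200 bp element, fast enough for every test
    paperlike — 13 strains + ancestor, 2472 bp element, two designed clades
    saturated — a sequence pair beyond TN93 validity (error-path testing)
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "strains": outdir / "strains.fasta",
        "reference": outdir / "reference.fasta",
        "truth_catalog": outdir / "truth_catalog.tsv",
        "true_tree": outdir / "true_tree.nwk",
        "metadata": outdir / "metadata.tsv",
        "config": outdir / "config.txt",
    }
    if name == "saturated":
        pair = saturated_pair(seed=seed)
        write_fasta(pair, paths["strains"])
        write_fasta(SequenceSet(entries=[pair.entries[0]]), paths["reference"])
        pd.DataFrame(
            [{"strain_id": sid, "species_label": "synthetic", "locale": "simulated",
              "accession": ""} for sid, _ in pair.entries]
        ).to_csv(paths["metadata"], sep="\t", index=False)
        write_config({"seed": seed}, paths["config"])
        return paths
    params = fixture_params(name, seed=seed)
    if name == "paperlike":
        params = replace(params, strain_tree=_paperlike_shared_root(params.strain_tree))
    seqs, truth = simulate_decay(params)
    write_fasta(seqs, paths["strains"])
    write_fasta(SequenceSet(entries=[("ancestor", truth.ancestral_element)]),
                paths["reference"])
    catalog_table(truth.catalogs).to_csv(paths["truth_catalog"], sep="\t", index=False)
    write_newick(truth.tree, paths["true_tree"])
    pd.DataFrame(
        [{"strain_id": sid, "species_label": sid.split("_")[0], "locale": "simulated",
          "accession": ""} for sid, _ in seqs.entries]
    ).to_csv(paths["metadata"], sep="\t", index=False)
    write_config(
        {"seed": seed, "nu": 0.0058, "generation_days": 30,
         "orf_start": params.orf_span[0], "orf_end": params.orf_span[1],
         "element_id_min": 99.0, "flank_id_min": 99.0, "signature_frac_min": 0.9},
        paths["config"],
    )
    return paths
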