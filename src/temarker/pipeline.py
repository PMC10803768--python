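"""Run orchestration and the conspecificity decision rule.

The caller is deliberately rule-based, not inferential: two strains are
called conspecific when they share the genomic insertion site (their
excised flank sequences align at high identity), their elements are nearly
identical, and their mutation catalogues share most reference-relative
signatures. No multiple-testing machinery applies — there is no test
statistic, only transparent thresholds, and the thresholds in force are
recorded in every report.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd

from . import align as _align
from . import element as _element
from . import evodist as _evodist
from . import phylo as _phylo
from .io import (
    StrainMeta,
    newick_string,
    read_alignment,
    read_config,
    read_fasta,
    read_metadata,
    write_config,
    write_matrix_tsv,
    write_newick,
)

log = logging.getLogger("temarker")


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds; the defaults sit in the observed gap between
    within-species (>99.5%) and between-lineage (~97%) element identity."""

    element_id_min: float = 99.0
    flank_id_min: float = 99.0
    signature_frac_min: float = 0.9

    def __post_init__(self) -> None:
        if not (0 <= self.element_id_min <= 100 and 0 <= self.flank_id_min <= 100):
            raise ValueError("identity thresholds must be in [0, 100]")
        if not 0 <= self.signature_frac_min <= 1:
            raise ValueError("signature_frac_min must be in [0, 1]")


@dataclass(frozen=True)
class ConspecificityCall:
    pair: tuple[str, str]
    element_identity: float | None
    flank_identity: float | None
    site_shared: bool
    shared_signature_fraction: float | None
    verdict: str  # conspecific | divergent_lineage | heterospecific_site | not_detected


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


def signature_fraction(a: _align.MutationCatalog, b: _align.MutationCatalog) -> float:
    """Fraction of the smaller catalogue's events carried identically by the
    other strain; 1.0 when the smaller catalogue is empty (vacuously shared).
    The denominator choice makes the measure robust to recent private
    mutations in the more-derived strain."""
    ka, kb = a.event_keys(), b.event_keys()
    denom = min(len(ka), len(kb))
    if denom == 0:
        return 1.0
    return len(ka & kb) / denom


def call_conspecificity(
    records: dict[str, _element.ElementRecord | None],
    catalogs: dict[str, _align.MutationCatalog],
    element_identity: pd.DataFrame,
    flank_identity: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> list[ConspecificityCall]:
    """Pairwise verdicts over all strains, symmetric in the pair.

    conspecific        — shared site, both identities and the shared-signature
                         fraction at or above threshold
    divergent_lineage  — shared site but some identity test fails
    heterospecific_site — element present but the flanks do not align
    not_detected       — at least one strain has no element record
    """
    strains = sorted(records)
    detected = [s for s in strains if records[s] is not None]
    for name, keys in (("catalogs", set(catalogs)),
                       ("element identity", set(element_identity.index)),
                       ("flank identity", set(flank_identity.index))):
        if not set(detected) <= keys:
            raise ValueError(f"{name} missing strains: {sorted(set(detected) - keys)}")
    calls = []
    for a, b in combinations(strains, 2):
        if records[a] is None or records[b] is None:
            calls.append(ConspecificityCall((a, b), None, None, False, None, "not_detected"))
            continue
        eid = float(element_identity.loc[a, b])
        fid = float(flank_identity.loc[a, b])
        frac = signature_fraction(catalogs[a], catalogs[b])
        site_shared = fid >= thresholds.flank_id_min
        if not site_shared:
            verdict = "heterospecific_site"
        elif (eid >= thresholds.element_id_min and fid >= thresholds.flank_id_min
              and frac >= thresholds.signature_frac_min):
            verdict = "conspecific"
        else:
            verdict = "divergent_lineage"
        calls.append(ConspecificityCall((a, b), eid, fid, site_shared, frac, verdict))
    return calls


def calls_table(calls: list[ConspecificityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain_a": c.pair[0],
                "strain_b": c.pair[1],
                "element_identity": None if c.element_identity is None
                else round(c.element_identity, 4),
                "flank_identity": None if c.flank_identity is None
                else round(c.flank_identity, 4),
                "site_shared": c.site_shared,
                "shared_signature_fraction": None if c.shared_signature_fraction is None
                else round(c.shared_signature_fraction, 4),
                "verdict": c.verdict,
            }
            for c in calls
        ]
    )


# -- full pipeline ---------------------------------------------------------

DEFAULTS = {
    "seed": 0,
    "nu": _evodist.DEFAULT_NU,
    "nu_ci_low": _evodist.DEFAULT_NU_CI[0],
    "nu_ci_high": _evodist.DEFAULT_NU_CI[1],
    "generation_days": _evodist.DEFAULT_GENERATION_DAYS,
    "element_id_min": 99.0,
    "flank_id_min": 99.0,
    "signature_frac_min": 0.9,
    "itr_min_len": _element.ITR_MIN_LEN,
    "itr_max_mismatch": _element.ITR_MAX_MISMATCH,
    "orf_start": _element.ORF_SPAN[0],
    "orf_end": _element.ORF_SPAN[1],
    "bootstrap_reps": 1000,
    "distance_model": "tn93",
    "lineage_split": "none",
}


def run_pipeline(config: dict | str | Path) -> Path:
    """Run every stage on a set of element+flank sequences and write a report.

    ``config`` is a flat mapping (or key=value file) naming at least
    ``reference`` (single-record FASTA of the functional ancestral element),
    ``elements`` (FASTA of per-strain full sequences) and ``outdir``.
    Every TSV written is byte-identical across reruns with the same config.
    """
    if not isinstance(config, dict):
        config = read_config(config)
    cfg = {**DEFAULTS, **config}
    for key in ("reference", "elements", "outdir"):
        if key not in cfg:
            raise PipelineError("config", f"missing required key {key!r}")
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, force=False)
    log.info("parameters in force: %s", {k: cfg[k] for k in sorted(cfg)})

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 — re-raised with stage context
            raise PipelineError(name, str(exc)) from exc

    ref_set = stage("read_reference", read_fasta, cfg["reference"])
    ref_id, reference = ref_set.entries[0]
    strains = stage("read_elements", read_fasta, cfg["elements"])
    if "metadata" in cfg:
        metas = {m.strain_id: m for m in stage("read_metadata", read_metadata, cfg["metadata"])}
    else:
        metas = {sid: StrainMeta(strain_id=sid) for sid in strains.ids}

    records: dict[str, _element.ElementRecord | None] = {}
    catalogs: dict[str, _align.MutationCatalog] = {}
    for sid, full in strains.entries:
        def annotate_one(sid=sid, full=full):
            rec = _element.annotate(
                metas.get(sid, StrainMeta(strain_id=sid)), full, reference,
                itr_min_len=cfg["itr_min_len"], itr_max_mismatch=cfg["itr_max_mismatch"],
                orf_span=(cfg["orf_start"], cfg["orf_end"]),
            )
            cat = _align.extract_catalog(_align.global_align(reference, rec.element_seq))
            return rec, cat
        records[sid], catalogs[sid] = stage(f"annotate[{sid}]", annotate_one)

    # element alignment: user-supplied MSA, or reference-pivoted stacking
    if "alignment" in cfg:
        msa = stage("read_alignment", read_alignment, cfg["alignment"])
        pivoted = False
    else:
        msa = stage("pivot_msa", _align.reference_pivot_msa, ref_id, reference, catalogs)
        pivoted = True
    element_identity = stage("identity", _align.identity_matrix, msa)

    flanks = {}
    for sid, rec in records.items():
        flanks[sid] = stage(f"excise[{sid}]", _element.excise_and_concat, rec).concatenated

    def flank_identity_matrix():
        ids = sorted(flanks)
        mat = pd.DataFrame(100.0, index=ids, columns=ids)
        for a, b in combinations(ids, 2):
            aln = _align.global_align(flanks[a], flanks[b])
            pid = _align.percent_identity(aln.ref_row, aln.qry_row)
            mat.loc[a, b] = mat.loc[b, a] = pid
        return mat

    flank_identity = stage("flank_identity", flank_identity_matrix)

    distances = stage("distances", _evodist.pairwise_distance_matrix, msa,
                      model=cfg["distance_model"])
    rates = _evodist.RateSpec(nu=cfg["nu"], nu_ci=(cfg["nu_ci_low"], cfg["nu_ci_high"]),
                              generation_days=cfg["generation_days"])
    divergence = stage("divergence", _evodist.divergence_table, msa, ref_id,
                       rates=rates, model=cfg["distance_model"],
                       lineage_split=cfg["lineage_split"])
    tree = stage("tree", _phylo.bootstrap_support, msa,
                 n_reps=cfg["bootstrap_reps"], seed=cfg["seed"],
                 model=cfg["distance_model"])
    thresholds = Thresholds(element_id_min=cfg["element_id_min"],
                            flank_id_min=cfg["flank_id_min"],
                            signature_frac_min=cfg["signature_frac_min"])
    calls = stage("call", call_conspecificity, records, catalogs,
                  element_identity, flank_identity, thresholds)

    annotation = pd.DataFrame(
        [
            {
                "strain": sid,
                "tsd_status": rec.tsd_status,
                "itr5_len": len(rec.itr5),
                "itr3_len": len(rec.itr3),
                "itr_intact": rec.itr_intact,
                "orf_status": rec.orf_status,
                "element_len": len(rec.element_seq),
                "flank5_len": len(rec.flank5),
                "flank3_len": len(rec.flank3),
                "concat_len": len(flanks[sid]),
            }
            for sid, rec in sorted(records.items())
        ]
    )

    write_matrix_tsv(element_identity, outdir / "identity_element.tsv")
    write_matrix_tsv(flank_identity, outdir / "identity_flank.tsv")
    write_matrix_tsv(distances, outdir / "distances.tsv", digits=6)
    divergence.round(6).to_csv(outdir / "divergence.tsv", sep="\t", index=False)
    annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    _align.catalog_table(catalogs).to_csv(outdir / "catalog.tsv", sep="\t", index=False)
    _align.shared_signature(catalogs).to_csv(outdir / "signatures.tsv", sep="\t", index=False)
    calls_table(calls).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    write_newick(tree, outdir / "tree.nwk")
    write_config({k: cfg[k] for k in sorted(cfg)}, outdir / "config_used.txt")

    verdict_counts = calls_table(calls)["verdict"].value_counts().to_dict()
    aln_note = (
        "reference-pivoted pairwise stacking (insertions relative to the "
        "reference are not columns)" if pivoted else "user-supplied MSA"
    )
    summary = [
        f"temarker report — {len(records)} strains vs reference {ref_id}",
        f"element alignment: {aln_note}",
        f"element identity range (off-diagonal): "
        f"{_offdiag_min(element_identity):.2f}-{_offdiag_max(element_identity):.2f}%",
        f"flank identity range (off-diagonal): "
        f"{_offdiag_min(flank_identity):.2f}-{_offdiag_max(flank_identity):.2f}%",
        f"verdicts: {verdict_counts}",
        f"thresholds: element>={thresholds.element_id_min}%, flank>={thresholds.flank_id_min}%, "
        f"signature fraction>={thresholds.signature_frac_min}",
        f"divergence (mean t): {divergence['t_Mgen'].mean():.2f} M generations, "
        f"{divergence['t_Myr'].mean():.2f} Myr "
        f"[nu={rates.nu}/site/Mgen, {rates.generation_days} d/generation]",
        f"tree: {newick_string(tree).strip()}",
        "",
    ]
    (outdir / "summary.txt").write_text("\n".join(summary))
    log.info("report written to %s", outdir)
    return outdir


def _offdiag_min(df: pd.DataFrame) -> float:
    import numpy as np

    vals = df.values[~np.eye(len(df), dtype=bool)]
    return float(vals.min())


def _offdiag_max(df: pd.DataFrame) -> float:
    import numpy as np

    vals = df.values[~np.eye(len(df), dtype=bool)]
    return float(vals.max())
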