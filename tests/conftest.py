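import dendropy
import pytest

from temarker.pipeline import run_pipeline
from temarker.simulate import (
    DecayParams,
    _paperlike_shared_root,
    fixture_params,
    make_fixture,
    simulate_decay,
)


@pytest.fixture(scope="session")
def tiny_sim():
    """Four strains, 200 bp element, with ground truth."""
    seqs, truth = simulate_decay(fixture_params("tiny", seed=7))
    return seqs, truth


@pytest.fixture(scope="session")
def paperlike_sim():
    """Thirteen strains in two designed element clades, 2472 bp element."""
    from dataclasses import replace

    params = fixture_params("paperlike", seed=11)
    params = replace(params, strain_tree=_paperlike_shared_root(params.strain_tree))
    seqs, truth = simulate_decay(params)
    return seqs, truth


@pytest.fixture(scope="session")
def paperlike_run(tmp_path_factory):
    """Full pipeline report on the paper-like fixture (run once per session)."""
    fixdir = tmp_path_factory.mktemp("fixture_paperlike")
    outdir = tmp_path_factory.mktemp("report_paperlike")
    paths = make_fixture("paperlike", fixdir, seed=11)
    report = run_pipeline(
        {
            "reference": str(paths["reference"]),
            "elements": str(paths["strains"]),
            "metadata": str(paths["metadata"]),
            "outdir": str(outdir),
            "seed": 11,
            "bootstrap_reps": 200,
        }
    )
    return report


def single_branch_params(t_generations: float, seed: int, **kw) -> DecayParams:
    """One descendant strain S at the given depth below the ancestor."""
    tree = dendropy.Tree.get(
        data=f"(S:{t_generations:.0f});", schema="newick", preserve_underscores=True
    )
    defaults = dict(strain_tree=tree, flank_len5=10, flank_len3=10, seed=seed)
    defaults.update(kw)
    return DecayParams(**defaults)
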