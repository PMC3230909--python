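import pytest

from srmdigest import (
    DigestParams,
    Experiment,
    generate_fixture,
    load_rules,
    read_fasta,
    read_sites_table,
    run_experiment,
)


@pytest.fixture(scope="session")
def registry():
    return load_rules()


@pytest.fixture()
def panel_dir(tmp_path):
    """A small synthetic 3-protein panel written to disk."""
    bundle = generate_fixture(
        seed=11, n_proteins=3, length=240, n_sites=6, motifs={"LysC": "K"}
    )
    bundle.write(tmp_path)
    return tmp_path, bundle


def build_experiments(fasta_path, sites_path, params=None):
    """Turn a panel on disk into one experiment per protein."""
    sequences = read_fasta(fasta_path)
    table = read_sites_table(sites_path, sequences)
    params = params or DigestParams()
    exps = []
    for pid, seq in sequences.items():
        exps.append(
            Experiment(
                name=f"exp-{pid}",
                protein_id=pid,
                sequence=seq,
                target_sites=table.for_protein(pid, seq),
                params=params,
            )
        )
    return exps


def run_panel(fasta_path, sites_path, registry, params=None):
    exps = build_experiments(fasta_path, sites_path, params)
    return [(exp, run_experiment(exp, registry)) for exp in exps]
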