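import pytest

from scopekit.barcode_design import assign_binary_codes, design_barcode_sets, generate_candidates


@pytest.fixture(scope="session")
def design():
    """Full two-role design at the default pool size (96 + 96 barcodes)."""
    return design_barcode_sets(n_per_role=96, seed=0)


@pytest.fixture(scope="session")
def small_code_maps():
    """Quick S/Q code maps (no self-complementarity cut) for decoder tests."""
    s_seqs = [c.sequence for c in generate_candidates(96, seed=11)]
    q_seqs = [c.sequence for c in generate_candidates(96, seed=22)]
    return assign_binary_codes(s_seqs, seed=11), assign_binary_codes(q_seqs, seed=22)
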