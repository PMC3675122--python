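"""Shared fixtures: a hand-built typing/sequence fixture and a small
simulated panel reused across test modules."""

import numpy as np
import pytest

from hlaimpute.markers import AlleleSequence, HlaTyping
from hlaimpute import simulate


@pytest.fixture(scope="session")
def mini_typings():
    """Six individuals typed at genes A and B (one partial, one 2-digit)."""
    return [
        HlaTyping("I1", "A", "A*0101", "A*0301"),
        HlaTyping("I1", "B", "B*0702", "B*0702"),
        HlaTyping("I2", "A", "A*0101", "A*0101"),
        HlaTyping("I2", "B", "B*0702", "B*0801"),
        HlaTyping("I3", "A", "A*0301", "A*2601"),
        HlaTyping("I3", "B", "B*0801", "B*1501"),
        HlaTyping("I4", "A", "A*0101", "A*2601"),
        HlaTyping("I4", "B", "B*1501", "B*1501"),
        HlaTyping("I5", "A", "A*01", "A*0301"),  # 2-digit-only first allele
        HlaTyping("I5", "B", "B*0702", "B*0801"),
        HlaTyping("I6", "A", None, None),  # missing call
        HlaTyping("I6", "B", "B*0702", "B*1501"),
    ]


@pytest.fixture(scope="session")
def mini_sequences():
    """Aligned 10-residue protein sequences for the alleles above.

    Polymorphisms planted at aligned positions 2 (D/A), 5 (S/G/R, three
    residues) and 8 (K/E); B*1501 carries a 2-residue deletion at 9-10.
    """
    return [
        AlleleSequence("A", "A*0101", "MDTWVLHAKL"),
        AlleleSequence("A", "A*0301", "MATWVLHAKL"),
        AlleleSequence("A", "A*2601", "MDTWVLHAEL"),
        AlleleSequence("B", "B*0702", "MYPRSGHWKV"),
        AlleleSequence("B", "B*0801", "MYPRGGHWKV"),
        AlleleSequence("B", "B*1501", "MYPRRGHW--"),
    ]


@pytest.fixture(scope="session")
def tiny_sim():
    """Small end-to-end simulation shared by integration-style tests."""
    cfg = simulate.SimConfig(
        n_founders=20, n_haplotypes=120, n_target=30, n_snps=400, seed=7
    )
    return simulate.simulate_panel(cfg)


@pytest.fixture(scope="session")
def tiny_imputation(tiny_sim):
    """Dense-profile imputation of the tiny simulation's target cohort."""
    from hlaimpute import hmm

    target, gold, truth = simulate.make_target(tiny_sim, profile="dense", seed=7)
    enc = [m.id for m in tiny_sim.panel.markers if m.kind != "SNP"]
    result = hmm.impute(target, tiny_sim.panel, markers=enc)
    return target, gold, truth, result
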