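import numpy as np
import pytest

from comparekit import (
    PWM, ExpressionMatrix, GenomicInterval, PromoterSet, ResponseVector,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_expr():
    """5 genes x 6 lines with one gene proportional to the response."""
    values = np.array([
        [-6.0, -5.8, -5.6, -5.4, -5.2, -5.0],   # == response (r = 1)
        [1.0, 2.0, 1.5, 2.5, 1.2, 2.2],
        [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],          # constant
        [2.0, 1.0, 2.5, 0.5, 2.8, 0.6],
        [0.1, 0.4, 0.2, 0.3, 0.25, 0.15],
    ])
    return ExpressionMatrix(
        gene_ids=["EQ", "POS", "CONST", "NEG", "NOISE"],
        cellline_ids=[f"L{i}" for i in range(1, 7)],
        values=values,
    )


@pytest.fixture
def small_resp():
    return ResponseVector(
        cellline_ids=[f"L{i}" for i in range(1, 7)],
        log10_ic50=np.array([-6.0, -5.8, -5.6, -5.4, -5.2, -5.0]),
    )


def make_pwm(motif_id="TOY", consensus="ACGTACG", strength=0.94):
    """Near-deterministic PWM whose max-probability path spells consensus."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(consensus)
    matrix = np.full((4, L), (1.0 - strength) / 3.0)
    for c, base in enumerate(consensus):
        matrix[idx[base], c] = strength
    return PWM(motif_id=motif_id, matrix=matrix)


def promoter_set_from_records(records, length):
    return PromoterSet(
        records=[
            (sid, GenomicInterval("chrSYN", 0, length, name=sid), seq)
            for sid, seq in records
        ],
        window=length,
    )


def random_pwm(rng, motif_id, length=7, concentration=0.7):
    probs = rng.dirichlet(np.full(4, concentration), size=length).T
    return PWM(motif_id=motif_id, matrix=probs / probs.sum(axis=0))
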