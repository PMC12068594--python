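import numpy as np
import pytest

from regconverge.motifs import PWM
from regconverge.promoters import PromoterRegion


@pytest.fixture
def aagt_pwm() -> PWM:
    """Sharp consensus-heavy motif AAGT with zero pseudocount (exact scores)."""
    counts = np.array(
        [
            [10, 0, 0, 0],
            [10, 0, 0, 0],
            [0, 0, 10, 0],
            [0, 0, 0, 10],
        ],
        dtype=float,
    )
    return PWM(tf_id="tfA", matrix=counts, pseudocount=0.0)


def make_promoter(seq: str, gene="g1", tx="g1.t1", strand="+", start=0):
    return PromoterRegion(
        gene_id=gene,
        transcript_id=tx,
        contig="chr_test",
        window_start=start,
        window_end=start + len(seq),
        strand=strand,
        sequence=seq,
        truncated=False,
    )


@pytest.fixture
def promoter_factory():
    return make_promoter


def random_pwm(rng: np.random.Generator, length: int, sharp: bool = False) -> PWM:
    """Random count PWM; 'sharp' concentrates mass on one base per column."""
    if sharp:
        mat = np.full((length, 4), 0.0)
        mat[np.arange(length), rng.integers(0, 4, size=length)] = 100.0
        pc = 0.5
    else:
        mat = rng.integers(0, 20, size=(length, 4)).astype(float)
        mat[mat.sum(axis=1) == 0, 0] = 1.0
        pc = 1.0
    return PWM(tf_id=f"rand{length}", matrix=mat, pseudocount=pc)


@pytest.fixture
def random_pwm_factory():
    return random_pwm
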