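import numpy as np
import pytest

from adiposeq import ExpressionMatrix, ExpressionSimSpec, generate_expression


@pytest.fixture(scope="session")
def planted_bundle():
    """Matrix + truth with strong planted effects (4-fold, 20% CV, n=6/group)."""
    spec = ExpressionSimSpec(
        n_transcripts=2000,
        frac_up=0.05,
        frac_down=0.02,
        effect_fold=4.0,
        noise_cv=0.2,
        seed=1,
    )
    return generate_expression(spec)


def make_matrix(rpkm, known=None, n_run=None):
    """Small two-group matrix helper: first half of columns RUN, rest LOCK."""
    rpkm = np.asarray(rpkm, dtype=float)
    n_t, n_s = rpkm.shape
    n_run = n_s // 2 if n_run is None else n_run
    sample_ids = [f"RUN_{i}" for i in range(n_run)] + [
        f"LOCK_{i}" for i in range(n_s - n_run)
    ]
    return ExpressionMatrix(
        transcript_ids=[f"t{i}" for i in range(n_t)],
        known=np.ones(n_t, bool) if known is None else known,
        rpkm=rpkm,
        sample_ids=sample_ids,
        group_of={s: ("RUN" if s.startswith("RUN") else "LOCK") for s in sample_ids},
    )
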