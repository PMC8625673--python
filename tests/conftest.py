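import numpy as np
import pandas as pd
import pytest

from lithopheno.cohort import AldaRecord, CohortParams, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the study-sample defaults (n=164, no planted effects)."""
    params = CohortParams(seed=3)
    records, table = generate_cohort(params)
    return params, records, table


def make_signal_records(seed: int, n: int = 300) -> list[AldaRecord]:
    """Cohort with a strong response signal carried by the B items.

    A latent responder state drives both a high A score and low confounder
    ratings, so the B items are informative about response — the regime in
    which a best-estimate tree is expected to reproduce the original
    categories.
    """
    rng = np.random.default_rng(seed)
    z = rng.random(n) < 0.35
    p_resp = [0.85, 0.12, 0.03]
    p_non = [0.25, 0.45, 0.30]
    records = []
    for i in range(n):
        if z[i]:
            a = int(rng.choice([9, 10]))
            b = rng.choice(3, size=5, p=p_resp)
        else:
            a = int(rng.choice(7))
            b = rng.choice(3, size=5, p=p_non)
        records.append(AldaRecord(
            subject_id=f"S{i:04d}", a_score=a,
            b1=int(b[0]), b2=int(b[1]), b3=int(b[2]), b4=int(b[3]), b5=int(b[4]),
            age=float(rng.normal(44.7, 12.3)), sex=str(rng.choice(["female", "male"])),
        ))
    return records


@pytest.fixture(scope="session")
def signal_records():
    return make_signal_records(seed=42)
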