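import numpy as np
import pytest

from lncarray import generate_reference, generate_study
from lncarray.reannotation import ProbeRecord, TranscriptRecord


def random_transcripts(rng, n, length=(200, 400), prefix="TX"):
    bases = np.array(list("ACGT"))
    out = []
    for i in range(n):
        L = int(rng.integers(*length))
        out.append(TranscriptRecord(f"{prefix}{i}", "".join(rng.choice(bases, L))))
    return out


@pytest.fixture(scope="session")
def clean_reference():
    """Small synthetic reference with no injected corruption."""
    return generate_reference(
        n_transcripts=25, n_probesets=15, mismatch_rate=0.0, ambiguous_rate=0.0, seed=11
    )


@pytest.fixture(scope="session")
def clean_study(clean_reference):
    ref = clean_reference
    target = ref.truth.probeset_map["PS0000_at"]
    return generate_study(
        ref,
        n_tumor=40,
        n_normal=40,
        de_transcripts={target: -2.0},
        noise_sd=0.4,
        beta_survival=np.log(0.5),
        censoring_fraction=0.3,
        seed=12,
    )
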