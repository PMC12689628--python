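import numpy as np
import pytest

from sleepedit import (EditSpec, gen_eeg_emg, gen_hypnogram)
from sleepedit.synthetic import HypnogramParams


@pytest.fixture(scope="session")
def amplicon():
    """A fixed 200-nt amplicon with a programmed C-to-T edit plus one silent
    mutation, and a quantification window wide enough to cover the +-20 nt
    indel zone of the read simulator."""
    rng = np.random.default_rng(20240917)
    ref = "".join(rng.choice(list("ACGT"), 200))
    ref = ref[:100] + "C" + ref[101:120] + "G" + ref[121:]
    spec = EditSpec(substitutions=[(100, "C", "T"), (120, "G", "A")],
                    window=(75, 146), name="A187V+SM")
    return ref, spec


@pytest.fixture(scope="session")
def short_recording():
    """A 2-h synthetic recording (ZT11-13: one light and one dark hour) with
    its generating hypnogram; shared across EEG tests for speed."""
    hyp = gen_hypnogram(HypnogramParams(hours=2.0, start_zt=11.0, seed=11))
    rec = gen_eeg_emg(hyp, fs=128.0, seed=12)
    return rec, hyp
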