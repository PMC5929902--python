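import numpy as np
import pytest

from spnpipe.core import Erp, Montage
from spnpipe import preprocess, synthetic_eeg


@pytest.fixture(scope="session")
def montage() -> Montage:
    return Montage.standard_64()


@pytest.fixture(scope="session")
def shared_timeline(montage):
    """Template segments identical across conditions; SPN the only condition
    difference (the amplitude-recovery configuration)."""
    return synthetic_eeg.default_timeline(
        montage, ["symmetry"], ["noise"], symmetry_only_map=None, seed=11)


@pytest.fixture(scope="session")
def small_epochsets(montage, shared_timeline):
    """4 participants x 2 conditions x 20 trials at 250 Hz."""
    return synthetic_eeg.simulate_epochs(
        ["symmetry", "noise"], shared_timeline, n_participants=4, seed=11,
        montage=montage, sfreq=250.0, n_trials=20)


def simulate_recovery_run(montage, seed, n_participants=24, n_trials=50,
                          sfreq=250.0, spn_uv=-1.5):
    """One scaled SPN-recovery run; see spnpipe.validation.spn_recovery_run."""
    from spnpipe.validation import spn_recovery_run

    return spn_recovery_run(seed, n_participants=n_participants,
                            n_trials=n_trials, sfreq=sfreq, spn_uv=spn_uv,
                            montage=montage)


def grand_average_erps(epochsets, conditions):
    """Grand-average common-average ERPs across participants."""
    erps = [preprocess.participant_erps(es) for es in epochsets]
    out = []
    for cond in conditions:
        g = np.mean([e[cond].data for e in erps], axis=0)
        e0 = erps[0][cond]
        out.append(Erp(data=g, condition=cond, n_epochs=len(erps),
                       montage=e0.montage, sfreq=e0.sfreq, tmin_ms=e0.tmin_ms,
                       reference="common-average", participant="grand"))
    return out, erps
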