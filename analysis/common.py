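"""Shared study configuration for the numbered analysis drivers.

All drivers analyse the same synthetic study: two arms (13 normal-sleep,
14 sleep-restricted subjects), 48 paired associates x 4 encoding
repetitions plus a recognition run, and 10 minutes of N3 per subject
(reduced from a full night so each driver runs in minutes).  The
sleep-restricted arm is planted with lower encoding stability but tighter
SO-spindle coupling, i.e. a negative stability -> coupling link across
subjects.
"""

from pathlib import Path

from repstab.config import SimConfig, StudyConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_config(seed: int = 7) -> StudyConfig:
    sim = SimConfig(sleep_minutes=10.0, coupling_kappa=1.0,
                    coupling_kappa_asr=8.0, seed=seed)
    return StudyConfig(sim=sim, n_perm=1000, seed=seed,
                       output_dir=str(RESULTS / "study"))
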