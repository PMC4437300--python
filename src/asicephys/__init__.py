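"""asicephys: acid-sensing ion channel physiology across amygdala cell types.

Analysis chain: current-clamp spike-train features -> Ward cell taxonomy;
nucleated-patch ASIC current density and kinetics (desensitization, Hill
pH response, reversal potential, tachyphylaxis); LTP quantification; fear
conditioning freezing scores; exact small-sample nonparametric tests.
A seeded synthetic-data layer (`asicephys.synth`) generates every input
class with planted parameters.
"""

from . import behavior, cluster, features, io, kinetics, plasticity, stats, synth
from .sweeps import SweepRecording

__version__ = "0.1.0"

__all__ = [
    "SweepRecording",
    "behavior",
    "cluster",
    "features",
    "io",
    "kinetics",
    "plasticity",
    "stats",
    "synth",
]
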