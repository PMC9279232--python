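"""Shared configuration for the numbered analysis scripts.

One reduced synthetic study is threaded through scripts 01-06: 300
patients, the full 11 biomarkers (10 gray-matter regions + lesion volume)
at one z-level each — so the two subtypes' event orderings are fully
reversed and well separated — with 60/40 mixing and noise SD 0.25
z-units.  Edit here to rerun the whole analysis at other sizes (e.g. the
generator's full three-level, 425-patient defaults: ``SimulationConfig()``).
"""

from pathlib import Path

from msstratify import SimulationConfig

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"
LESION = "tlv"

CONFIG = SimulationConfig(
    n_patients=300,
    n_hc=100,
    n_external=60,
    levels=(1.0,),
    sigma_gen=0.25,
)
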