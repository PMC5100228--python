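"""Shared paths and the study configuration used by the numbered drivers."""

from pathlib import Path

from tagdge.synthetic_data import SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "analysis" / "data"
OUT = ROOT / "results" / "analysis"

# the emulated design: two cultivars x (control, chromium, chromium+GSH),
# duplicate libraries of 10^6 tags over 5,000 genes, 200 planted DE genes
# perturbed by the chromium treatment
STUDY = SimulationConfig(seed=20160101)

CONTRASTS = [
    ("ZS758_Cr_vs_Ck", "ZS758_Ck", "ZS758_Cr"),
    ("ZS758_CrGSH_vs_Ck", "ZS758_Ck", "ZS758_CrGSH"),
    ("Zheda622_Cr_vs_Ck", "Zheda622_Ck", "Zheda622_Cr"),
    ("Zheda622_CrGSH_vs_Ck", "Zheda622_Ck", "Zheda622_CrGSH"),
    ("Zheda622_vs_ZS758_Ck", "ZS758_Ck", "Zheda622_Ck"),
    ("Zheda622_vs_ZS758_Cr", "ZS758_Cr", "Zheda622_Cr"),
]
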