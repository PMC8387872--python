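"""Reference material parameter sets used by examples, the demo and tests.

Values are published fits for spinal cord white matter (one-term Ogden with a
three-term normalized Prony series) and pia mater (one-term Ogden, quasi-static
tension).
"""

from __future__ import annotations

from .constitutive import OgdenModel, PronySeries, QLVMaterial

__all__ = [
    "CORD_OGDEN",
    "CORD_PRONY",
    "CORD_QLV",
    "PIA_OGDEN",
    "CORD_COMPRESSION_RATES",
    "PIA_TENSION_RATE",
]

#: One-term Ogden backbone for spinal cord white matter: mu = 209 Pa, alpha = 7.52.
CORD_OGDEN = OgdenModel(terms=[(209.0, 7.52)], poisson_ratio=0.499)

#: Normalized Prony relaxation for the cord: (G_i, beta_i [1/s]).
CORD_PRONY = PronySeries(terms=[(0.033, 2.0), (0.296, 13.0), (0.406, 406.0)])

#: Cord hyper-viscoelastic material (normalized QLV formulation).
CORD_QLV = QLVMaterial(elastic=CORD_OGDEN, relaxation=CORD_PRONY)

#: One-term Ogden fit for pia mater: mu = 42 kPa, alpha = 12.58.
PIA_OGDEN = OgdenModel(terms=[(42_000.0, 12.58)], poisson_ratio=0.49)

#: Nominal engineering strain rates of the cord compression experiments [1/s].
CORD_COMPRESSION_RATES = (0.32, 2.83, 25.44, 77.22)

#: Quasi-static strain rate of the pia tension experiment [1/s].
PIA_TENSION_RATE = 0.05
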