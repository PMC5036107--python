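"""Published pan-cancer site-recurrence tallies used as reference inputs.

Observed counts of genomic sites hit 0-7 times by the 3.4M pooled somatic
SNVs of 507 whole cancer genomes (hg19, SSR-masked), per genomic fraction
(TE / NTE / EX), at three mappability strata: all interrogable sites, sites
uniquely mappable at 100 bp, and sites uniquely mappable at 20 bp.  Together
with the fraction sizes in base pairs, these printed tallies let the
bookkeeping operations (SNV totals, excess-site counts and densities,
stratification reductions) be recomputed exactly without the 2.8 Gb inputs.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .recurrence import RecurrenceSpectrum

__all__ = [
    "FRACTION_SIZES_BP",
    "OBSERVED_SPECTRA",
    "observed_spectra",
]

#: Interrogable (SSR-excluded) fraction sizes of the reference genome, bp.
FRACTION_SIZES_BP: Dict[str, int] = {
    "TE": 1_346_629_686,
    "NTE": 1_322_985_768,
    "EX": 119_806_141,
}

#: Observed n_x (sites hit exactly x times, x = 0..7) per stratum and fraction.
OBSERVED_SPECTRA: Dict[str, Dict[str, tuple]] = {
    "all": {
        "TE": (1_344_972_042, 1_649_680, 7_034, 762, 130, 26, 9, 3),
        "NTE": (1_321_454_397, 1_527_967, 3_171, 188, 35, 6, 2, 2),
        "EX": (119_708_384, 97_488, 245, 23, 0, 0, 1, 0),
    },
    "unique@100": {
        "TE": (1_223_239_922, 1_517_676, 3_927, 266, 25, 11, 5, 1),
        "NTE": (1_276_165_087, 1_499_761, 2_698, 97, 16, 2, 0, 1),
        "EX": (112_360_615, 93_084, 185, 16, 0, 0, 0, 0),
    },
    "unique@20": {
        "TE": (388_613_299, 480_820, 741, 9, 0, 0, 0, 0),
        "NTE": (892_370_709, 1_061_716, 1_621, 31, 4, 1, 0, 1),
        "EX": (74_735_962, 61_034, 103, 6, 0, 0, 0, 0),
    },
}


def observed_spectra(stratum: str = "all") -> Dict[str, RecurrenceSpectrum]:
    """The published fraction-level observed spectra for one stratum."""
    return {
        frac: RecurrenceSpectrum(frac, None, np.array(counts, dtype=np.int64))
        for frac, counts in OBSERVED_SPECTRA[stratum].items()
    }
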