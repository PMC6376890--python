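"""Reference (MSE, PSNR) pairs from a published MRI de-noising comparison.

These printed figures serve one purpose here: validating that this
package's PSNR formula, ``10*log10(255**2/MSE)``, reproduces each
published PSNR from its published MSE.  Pairs whose printed values are not
self-consistent under that formula (obvious typesetting errors, listed in
``INCONSISTENT_MSE_PSNR_PAIRS``) are excluded from the check but kept for
documentation.

Each entry is ``(table, rule, noise_variance, mse, psnr_db)`` where the
noise variance is on the unit intensity scale.
"""

from __future__ import annotations

from typing import List, Tuple

__all__ = ["CONSISTENT_MSE_PSNR_PAIRS", "INCONSISTENT_MSE_PSNR_PAIRS"]

Cell = Tuple[int, str, float, float, float]

#: Pairs that satisfy PSNR = 10*log10(255^2/MSE) to within +/- 0.01 dB.
CONSISTENT_MSE_PSNR_PAIRS: List[Cell] = [
    (1, "hard", 0.01, 310, 23.21),
    (1, "hard", 0.03, 603, 20.33),
    (1, "hard", 0.05, 643, 20.05),
    (1, "soft", 0.03, 765, 19.29),
    (1, "soft", 0.05, 771, 19.26),
    (1, "soft", 0.10, 1627, 16.01),
    (1, "improved", 0.01, 147, 26.46),
    (1, "improved", 0.03, 311, 23.20),
    (1, "improved", 0.10, 625, 20.17),
    (2, "hard", 0.01, 624, 20.18),
    (2, "hard", 0.03, 780, 19.21),
    (2, "hard", 0.05, 910, 18.54),
    (2, "improved", 0.01, 206, 24.99),
    (2, "improved", 0.03, 338, 22.84),
    (2, "improved", 0.05, 483, 21.29),
    (3, "hard", 0.05, 549, 20.74),
    (3, "soft", 0.01, 465, 21.46),
    (3, "soft", 0.03, 422, 21.88),
    (3, "soft", 0.05, 647, 20.02),
    (3, "soft", 0.10, 1308, 16.96),
    (3, "improved", 0.01, 180, 25.58),
    (3, "improved", 0.03, 133, 26.89),
    (3, "improved", 0.05, 287, 23.55),
    (3, "improved", 0.10, 631, 20.13),
]

#: Pairs whose printed MSE and PSNR contradict the formula by more than
#: 0.01 dB — treated as printing errors and excluded from validation.
INCONSISTENT_MSE_PSNR_PAIRS: List[Cell] = [
    (1, "hard", 0.10, 1495, 16.49),
    (1, "soft", 0.01, 386, 22.64),
    (1, "improved", 0.05, 341, 23.20),
    (2, "hard", 0.10, 1136, 16.49),
    (2, "soft", 0.01, 740, 22.64),
    (2, "soft", 0.03, 952, 19.29),
    (2, "soft", 0.05, 1080, 19.26),
    (2, "soft", 0.10, 1530, 16.01),
    (2, "improved", 0.10, 668, 19.83),
    (3, "hard", 0.01, 387, 22.53),
    (3, "hard", 0.03, 350, 22.67),
    (3, "hard", 0.10, 1022, 17.77),
]
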