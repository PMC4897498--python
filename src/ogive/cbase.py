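"""Published 2PNO posterior estimates for the first ten CBASE items.

The College Basic Academic Subjects Examination (CBASE) is a criterion-
referenced achievement test; a widely circulated calibration of its LP form
(3,356 examinees, 2001-2002 administrations) reports posterior means and
Monte Carlo standard errors for the item slopes and intercepts of the
first ten items, together with the difficulty ratios beta/alpha.  The raw
response data are not deposited; the printed summaries below serve purely
as arithmetic fixtures — e.g. checking that the difficulty-ratio
computation reproduces the published ratio column from the published
slope and intercept columns at 4-decimal rounding.
"""

import numpy as np

__all__ = ["ITEMS", "ALPHA_HAT", "ALPHA_MCSE", "BETA_HAT", "BETA_MCSE", "RATIO"]

ITEMS = np.arange(1, 11)

ALPHA_HAT = np.array(
    [0.4280, 0.2993, 0.3316, 0.3061, 0.3952, 0.7231, 0.3302, 0.4612, 0.4669, 0.4943]
)
ALPHA_MCSE = np.array(
    [0.0013, 0.0005, 0.0002, 0.0015, 0.0009, 0.0018, 0.0006, 0.0009, 0.0007, 0.0008]
)
BETA_HAT = np.array(
    [-0.5273, -0.5884, -1.0379, -1.2878, -1.1658, -0.8883, -0.4362, -1.1996, -0.1065, -0.0358]
)
BETA_MCSE = np.array(
    [0.0009, 0.0004, 0.0003, 0.0008, 0.0014, 0.0013, 0.0006, 0.0008, 0.0005, 0.0008]
)
RATIO = np.array(
    [-1.2320, -1.9659, -3.1300, -4.2071, -2.9499, -1.2285, -1.3210, -2.6010, -0.2281, -0.0724]
)
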