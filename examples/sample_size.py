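"""How many videos does a reliability study need?

Bonett's precision method: choose n so the 95% CI of the estimated ICC is
no wider than the target.  With a planning ICC of 0.7 and five raters per
video, estimating within +/-0.1 takes 51 videos.
"""

from rragree import SampleSizeSpec, bonett_n

for half_width in (0.05, 0.1, 0.15, 0.2):
    spec = SampleSizeSpec(rho=0.7, k=5, half_width=half_width)
    print(f"ICC 0.7, 5 raters, +/-{half_width:<4} -> n = {bonett_n(spec):>3} videos")
# Halving the tolerated half-width roughly quadruples the required n,
# as expected from the 1/w^2 dependence.
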