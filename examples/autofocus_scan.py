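"""Score sharpness through a defocus series and run the autofocus search.

The Tenengrad (squared Sobel gradient) and intensity-variance metrics peak
at best focus. The autofocus routine does a coarse grid sweep and refines
around the coarse optimum, as a stage-driven microscope would.
"""

import numpy as np

from microlapse import SimConfig, autofocus, simulate_defocus_series, tenengrad, variance_metric

cfg = SimConfig(shape=(128, 128), seed=5)
z_true = 1.5

positions = list(np.linspace(-5.0, 5.0, 11))
series = simulate_defocus_series(cfg, positions, z_true=z_true, blur_per_z=1.0)

print(" z      tenengrad    variance")
for z, frame in zip(positions, series):
    print(f"{z:5.1f}  {tenengrad(frame).value:10.1f}  {variance_metric(frame).value:9.2f}")

provider = lambda z: simulate_defocus_series(cfg, [z], z_true=z_true, blur_per_z=1.0)[0]  # noqa: E731
result = autofocus(provider, (-5.0, 5.0), coarse_step=1.0, fine_step=0.25)
print(f"\nautofocus best position : {result.best_position}  (true focus {z_true})")
print(f"metric evaluations      : {result.n_evaluations}")
# Both metrics fall monotonically with defocus blur; the two-stage search
# lands on the true focal position using ~17 evaluations instead of 41.
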