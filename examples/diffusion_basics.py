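"""Forward diffusion, x0 recovery, and the denoising posterior on scalars.

Builds a short linear variance schedule, pushes a scalar through the
closed-form forward process, inverts it exactly, and prints the posterior
mean/variance of one denoising step.
"""

import numpy as np

from longidiff.diffusion import (estimate_x0, forward_sample, make_schedule,
                                 posterior_params)

sched = make_schedule(T=10, beta_start=0.01, beta_end=0.3)
print("alpha_bar:", np.round(sched.alpha_bar, 4))
print("terminal alpha_bar (signal kept at t=T):", round(sched.abar(10), 4))

x0 = np.array(0.7)
eps = np.array(1.2)
t = 6
xt = forward_sample(x0, t, eps, sched).x_t
print(f"\nx0={float(x0)}, eps={float(eps)}, t={t} -> x_t={float(xt):.4f}")

rec = estimate_x0(xt, t, eps, sched)
print(f"estimate_x0 inverts the forward draw exactly: {float(rec):.12f}")

mean, var = posterior_params(xt, t, eps, sched)
print(f"\ndenoising posterior at t={t}: mean={float(mean):.4f}, var={var:.4f}")
print("(the mean interpolates between the x0 estimate and x_t; the variance")
print(" is the closed-form posterior variance beta~_t)")
mean1, var1 = posterior_params(xt, 1, eps, sched)
print(f"at t=1 the transition is deterministic: var={var1}")
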