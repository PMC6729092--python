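"""Sample-size and power computations for the smoothness group contrast.

The a-priori design question: how many subjects per group does a two-sample
t-test need to detect a mean SPARC difference of 1.57 at SD 0.79 (Cohen
d ~= 1.99) with 90% power at alpha 0.05?  One-tailed, the noncentral-t
answer is 6 per group; the script also shows the achieved power of the
realized unbalanced 31-vs-6 design for the observed effect.
"""

from itug import PowerSpec, achieved_power_ttest, cohen_d, power_ttest, required_n_ttest

d_planned = 1.57 / 0.79
spec = PowerSpec(effect_size=d_planned, alpha=0.05, power=0.90, tails=1)
n = required_n_ttest(spec)
print(f"planned effect d = {d_planned:.4f}")
print(f"required n per group (one-tailed, 90% power): {n}")
print(f"power actually reached at n = {n}: "
      f"{power_ttest(d_planned, n, n, 0.05, tails=1):.3f}")
print(f"two-tailed convention would need: "
      f"{required_n_ttest(PowerSpec(effect_size=d_planned, tails=2))} per group")

# retrospective power of an unbalanced design for a smaller observed effect
d_observed = 2.11 / 1.9
retro = achieved_power_ttest(
    PowerSpec(effect_size=d_observed, alpha=0.05, tails=2), n1=31, n2=6
)
print(f"\nobserved effect d = {d_observed:.3f}: power of a 31-vs-6 design "
      f"(two-tailed) = {retro:.2f}")
print("Unbalanced groups cost power: the smaller arm dominates the precision.")
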