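"""Recover (mu, nu, t) from observed length summaries by the candidate-t
scan: nu_t = t/lambda^-1, mu_t from inverting the shape law, beta_t from
the rate law, and t_hat = argmin |beta - beta_t| / beta.

The observables below are a reference worked example from a run at
mu = 1, nu = 3, t = 5.
"""

from fractionate import Observables, infer

obs = Observables(lambda_inv=1.665595, alpha=0.6711252, beta=0.3504422)
result = infer(obs, t_range=range(3, 8))

print("t    mu_t      nu_t      beta_t    100*delta")
for row in result.table():
    print(
        f"{row['t']}  {row['mu_t']:.6f}  {row['nu_t']:.6f}  "
        f"{row['beta_t']:.6f}  {row['delta_x100']:.4f}"
    )
print()
print(f"t_hat = {result.t_hat}, mu_hat = {result.mu_hat:.4f}, "
      f"nu_hat = {result.nu_hat:.4f}")
print()
print("The discrepancy 100*delta dips at t = 5: five sweeps with mu ~ 1.02")
print("and nu ~ 3.00 explain the observed length distributions best,")
print("matching the parameters that generated them.")
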