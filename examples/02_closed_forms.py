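"""Closed-form results of the model, printed as small tables.

lambda_t = nu/t is the mean spacing of surviving deletion points after t
sweeps; p_q is the geometric law for the number of pre-existing deletion
points a new deletion swallows; pi_t(i) is the proportion of event
counters equal to i, propagated sweep by sweep.
"""

from fractionate import lambda_exact, overlap_pmf, pi_trajectory, retained_proportion

mu, nu = 1.0, 3.0

print("t   lambda_t   retained=(1-mu/(nu+mu))^t")
for t in range(1, 6):
    print(f"{t}   {lambda_exact(nu, t):8.4f}   {retained_proportion(mu, nu, t):8.4f}")

print()
lam = lambda_exact(nu, 2)  # spacing among points existing during sweep 3
print(f"overlap law at lambda = {lam} (sweep 3):  p_q = "
      "lam/(mu+lam) * (mu/(mu+lam))^q")
for q in range(5):
    print(f"  q={q}: {overlap_pmf(q, mu, lam):.4f}")

print()
print("event-count distribution pi_t(i) (counters merged per deletion):")
traj = pi_trajectory(mu, nu, 5, i_max=64)
print("t  " + "  ".join(f"pi({i})" for i in range(1, 6)))
for t, pi in enumerate(traj, start=1):
    print(f"{t}  " + "  ".join(f"{pi[i]:.4f}" for i in range(1, 6)))

print()
print("After sweep 1 every counter is 1; later sweeps merge counters, so")
print("mass flows to larger i while new single-event counters keep i=1")
print("dominant.")
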