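"""Simulate an adapting population with and without a seed bank.

Runs the three-step Wright-Fisher model (metabolic exchange, beneficial
mutation, multinomial selection) at desk scale and contrasts the fate of
diversity with a large vs a small dormant compartment.
"""

import numpy as np

import seedbankevo as se

for D in (100, 10_000):
    params = se.SeedBankParams(
        A=10_000, D=D, c=10.0,
        Ub=3.28e-11, Lgenome=4.29e6, dfe_scale=1e-2,
        generations=500, seed=1,
    )
    res = se.run_simulation(params, sampling_interval=10)
    ids, mat = res.frequency_array()
    fmax = mat.max(axis=1) if len(ids) else np.array([0.0])
    print(f"D={D:6d}  <Td>={se.mean_dormancy_time(params):7.0f} generations")
    print(f"  mutations arisen: {len(ids)}  mean supply/gen: "
          f"{res.mutation_supply.mean():.2f} (theory {params.A*params.Ub*params.Lgenome:.2f})")
    print(f"  max combined frequency reached: {fmax.max():.3f}")
    print(f"  mean dwell time sampled: {res.dwell_times.mean():.1f} "
          f"(theory D/c = {D/10:.0f})")

print(
    "\nA larger seed bank (longer mean dormancy <Td>) buffers allele-"
    "frequency change:\nthe same mutation supply reaches much lower "
    "population-wide frequencies because\ndormant genomes dilute and lag the "
    "sweeps occurring among active cells."
)
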