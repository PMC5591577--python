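"""Relative binding free energy of a substituent mutation in the toy
pocket, via the thermodynamic cycle.

The F -> Cl mutation at the ligand's meta position is run in two legs:
bound in the pocket complex (with the flexible pocket rotor in the REST
hot region) and as the free ligand.  ddG = dG_complex - dG_unbound is
the relative binding free energy: negative means Cl binds tighter than
F in this model pocket, positive means the pocket rewards the larger
halogen less than the free ligand does.
"""

from restfep import ChainConfig, LambdaSchedule, ReplicaLadder
from restfep.fep import BindingCycle, Leg, run_leg
from restfep.model_systems import (
    make_pocket_complex,
    make_unbound_ligand,
    substituent_map,
)
from restfep.sampler import default_move_mix

schedule = LambdaSchedule.uniform(11)
ladder = ReplicaLadder.geometric(n_replicas=6, t_max=1200.0, swap_every=100)
cfg = ChainConfig(n_steps=6_000, seed=1, record_every=10)

complex_system = make_pocket_complex(substituent="F")
unbound = make_unbound_ligand(substituent="F")
amap = substituent_map(complex_system, "F", "CL")

complex_leg = run_leg(complex_system, amap, schedule,
                      default_move_mix(complex_system), cfg,
                      leg=Leg.COMPLEX, ladder=ladder)
unbound_leg = run_leg(unbound, amap, schedule,
                      default_move_mix(unbound), cfg, leg=Leg.UNBOUND)
cycle = BindingCycle(complex_leg, unbound_leg)

print(f"dG_mut(complex) = {complex_leg.total:+.3f} +/- "
      f"{complex_leg.stderr:.3f} kcal/mol (hysteresis "
      f"{complex_leg.hysteresis:.3f})")
print(f"dG_mut(unbound) = {unbound_leg.total:+.3f} +/- "
      f"{unbound_leg.stderr:.3f} kcal/mol")
print(f"ddG_bind(F->Cl) = {cycle.ddg:+.3f} +/- {cycle.stderr:.3f} kcal/mol")
print("The sign says which environment rewards the mutation more: the")
print("pocket (ddG < 0, Cl binds tighter) or the free state (ddG > 0).")
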