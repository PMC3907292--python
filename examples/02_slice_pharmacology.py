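"""Slice paradigms: tonic dopamine and tonic NMDA-driven Ca²⁺.

Bathing striatal slices in 10 µM dopamine drives PKA and multiplies
DARPP-32 phospho-Thr34 roughly twelve-fold within five minutes while
phospho-Thr75 halves; bath NMDA (modelled as a tonic 10 µM Ca²⁺ elevation)
instead halves phospho-Thr34 through calcineurin.
"""
from msnsig.experiments import ModelSession
from msnsig.phenotypes import marker_value, readout

ses = ModelSession(scheme="010")
traj0 = type("T", (), {"net": ses.net, "params": ses.params, "scaling": None})
base34 = marker_value(traj0, "D32p34", ses.basal)
base75 = marker_value(traj0, "D32p75", ses.basal)

da = ses.run("WT", "DAslice", duration=300.0, readout_s=(300.0,))
nm = ses.run("WT", "NMDAslice", duration=600.0, readout_s=(600.0,))
print(f"DAslice  (5'): D32p34 x{readout(da,'D32p34',300.)/base34:5.1f}, "
      f"D32p75 x{readout(da,'D32p75',300.)/base75:4.2f}")
print(f"NMDAslice(10'): D32p34 x{readout(nm,'D32p34',600.)/base34:5.2f}, "
      f"D32p75 x{readout(nm,'D32p75',600.)/base75:4.2f}")
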