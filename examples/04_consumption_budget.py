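"""Drop-volume and sample-consumption arithmetic with the Poisson
occupancy model.

An 80 µm spherical drop holds ~268 pl (commonly quoted rounded to 250 pl);
at 60 Hz that is under 1 µl per minute — orders of magnitude below a
continuous jet. The same drop volume times an interaction fraction sets
the Poisson mean of crystals per probed volume, which links slurry
concentration to the observed hit rate.
"""

from dropsfx import (ConsumptionModel, drop_volume_from_diameter,
                     estimate_concentration, volumetric_rate)

v80 = drop_volume_from_diameter(80.0)
print(f"80 um drop volume      : {v80:.2f} pl")
print(f"consumption, 250 pl@60Hz: {volumetric_rate(250.0, 60.0):.3f} ul/min")
print(f"consumption, 250 pl@1.2kHz: {volumetric_rate(250.0, 1200.0):.1f} ul/min")

model = ConsumptionModel(drop_diameter_um=80.0, repetition_rate_hz=60.0,
                         concentration_per_nl=400.0, interaction_fraction=0.02)
report = model.report()
print(f"lambda (crystals/probe) : {report['lambda']:.3f}")
print(f"P(hit)                  : {report['p_hit']:.3f}")
print(f"P(multi-crystal | hit)  : {report['p_multi_given_hit']:.3f}")

# invert an observed hit rate back to a concentration estimate
rate_pct = 100.0 * report["p_hit"]
c_hat = estimate_concentration(rate_pct, model.probed_volume_nl)
print(f"concentration recovered from the {rate_pct:.1f}% hit rate: "
      f"{c_hat:.1f} crystals/nl")
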