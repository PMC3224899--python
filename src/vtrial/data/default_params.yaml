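# Population constants for the ICU glucose-insulin system model.
# Values are literature-typical for this model family and are deliberately
# kept in a config file: no constant is hard-coded in computation paths.
#
# Units are noted per key. Internal time unit is minutes.

pG: 0.006        # non-insulin-mediated glucose clearance (1/min)
alphaG: 0.0154   # insulin-effect saturation, 1/65 (L/mU)
alphaI: 0.0017   # plasma insulin clearance saturation (L/mU)
n: 0.16          # plasma insulin decay rate (1/min)
k: 0.0542        # plasma -> interstitial insulin transport rate (1/min)
EGPmax: 1.16     # maximum endogenous glucose production (mmol/min)
CNS: 0.30        # central-nervous-system glucose uptake (mmol/min)
VG: 13.3         # glucose distribution volume (L)
VI: 3.15         # insulin distribution volume (L)
IB: 1.9          # basal endogenous insulin appearance (mU/L/min, see ib_units)
kI: 0.0017       # exponential suppression of endogenous insulin per unit
                 # exogenous infusion (min/mU)
d1: 0.0347       # stomach -> gut glucose transport (1/min)
d2: 0.0069       # gut absorption to plasma (1/min)

# IB convention: "per_volume" treats IB as an appearance rate per unit insulin
# distribution volume (mU/L/min), making the insulin ODE dimensionally
# consistent as written.  "total" treats IB as mU/min and divides by VI at load.
ib_units: per_volume
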