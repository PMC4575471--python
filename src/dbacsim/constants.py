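"""Program-level performance requirements for the DBAC cuff.

These are the quantitative targets the cuff system has to meet: thermal dose
window at the bleeder, skin-temperature ceiling, lateral heating confinement,
structural and velocity resolution of the detection subsystem, and the limb
size range the cuff must wrap. They are used for pass/fail bookkeeping
throughout the package and are never silently overridden.
"""

# Thermal dose requirements (temperature elevations above baseline, in deg C).
MIN_TD_DT_LOW_C = 33.0     # minimum end-of-dose rise at the target (MinTD lower bound)
MIN_TD_DT_HIGH_C = 58.0    # ceiling that keeps peak temperature below boiling
MTSD_DT_C = 20.0           # maximum thermal skin dose: skin rise must stay at or below this
MTTD_RADIUS_MM = 10.0      # no significant heating outside this lateral radius (MTTD)
MTV_DIAMETER_MM = 8.0      # minimum therapeutic volume: spherical region that must reach MinTD
MAX_DOSE_TIME_S = 30.0     # single-dose exposure limit

# Detection and localization requirements.
MSR_MM = 0.6               # minimum structure resolution: smallest vessel diameter
MDV_CM_S = 3.0             # minimum detectable (mean) flow velocity
RI_BLEEDER_THRESHOLD = 0.75  # resistive index strictly below this classifies a bleeder
TARGETING_TOL_MM = 3.0     # closed-loop targeting convergence tolerance

# Limb geometry range (radius-of-curvature and depth-of-penetration bounds, cm).
MIN_RC_CM = 3.75
MAX_RC_CM = 12.5
MIN_LIMB_DIAMETER_CM = 2 * MIN_RC_CM
MAX_LIMB_DIAMETER_CM = 2 * MAX_RC_CM
MIN_DP_CM = 3.75
MAX_DP_CM = 12.5

# Skin exposure limit used to cap per-tile acoustic output.
SKIN_INTENSITY_LIMIT_W_CM2 = 6.0
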