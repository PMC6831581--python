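"""Study constants: muscle set, targets and task phases."""

#: The 13 recorded muscles of the right shoulder girdle and upper arm, in
#: fixed channel order: upper/middle/lower trapezius, anterior/middle/
#: posterior deltoid, pectoralis major, biceps short/long head, triceps
#: lateral/long head, brachioradialis, sterno-cleido-occipito-mastoideus.
MUSCLES: tuple[str, ...] = (
    "TU", "TM", "TL", "DA", "DM", "DP", "PM",
    "BS", "BL", "TLA", "TLO", "BR", "SCOM",
)

#: Radial target angles (degrees) of the center-out reaching task.
TARGET_ANGLES: tuple[float, ...] = tuple(float(a) for a in range(0, 360, 45))

#: Inertial sensor placements.
SENSOR_POSITIONS: tuple[str, ...] = ("sternum", "shoulder", "arm", "forearm")

#: Kinematic variables recorded per sensor.
KINEMATIC_VARIABLES: tuple[str, ...] = (
    "acc_x", "acc_y", "acc_z", "roll", "pitch", "yaw",
)

#: Trigger-point status levels.
TP_LEVELS: tuple[str, ...] = ("ACT", "LAT", "NO")

#: Number of samples each movement is resampled to before concatenation.
MOVEMENT_SAMPLES: int = 200
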