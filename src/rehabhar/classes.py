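"""Exercise classes and sensor channel subsets.

The recognizer distinguishes four bilateral upper-limb rehabilitation
exercises plus a no-exercise (rest) class.  Class indices are fixed:
they define the order of the softmax output nodes and of confusion
matrix rows/columns everywhere in the package.
"""

from __future__ import annotations

import enum


class ExerciseClass(enum.IntEnum):
    """The five activity classes, index 0..4 with rest first."""

    NO_EXERCISE = 0
    BILATERAL_FLEXION = 1
    WALL_PUSH = 2
    ACTIVE_SCAPULA = 3
    TOWEL_SLIDE = 4

    @classmethod
    def from_name(cls, name: str) -> "ExerciseClass":
        try:
            return cls[name]
        except KeyError:
            raise ValueError(
                f"unknown exercise class {name!r}; expected one of "
                f"{[c.name for c in cls]}"
            ) from None


#: The four active exercises, in index order (rest excluded).
EXERCISES = tuple(c for c in ExerciseClass if c is not ExerciseClass.NO_EXERCISE)

#: Fixed channel order of a full 6-axis sample.
CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")


class SensorSubset(enum.Enum):
    """Which IMU channels feed the classifier.

    Channel order is fixed: accelerometer (ax, ay, az) before
    gyroscope (gx, gy, gz); the combined subset concatenates them.
    """

    ACCEL = ("ax", "ay", "az")
    GYRO = ("gx", "gy", "gz")
    ACCEL_GYRO = ("ax", "ay", "az", "gx", "gy", "gz")

    @property
    def channels(self) -> tuple[str, ...]:
        return self.value

    @property
    def n_channels(self) -> int:
        return len(self.value)

    @property
    def indices(self) -> tuple[int, ...]:
        """Column indices into the full (ax..gz) channel layout."""
        return tuple(CHANNELS.index(c) for c in self.value)

    @classmethod
    def from_string(cls, s: str) -> "SensorSubset":
        key = s.strip().lower()
        aliases = {
            "accel": cls.ACCEL,
            "a": cls.ACCEL,
            "gyro": cls.GYRO,
            "g": cls.GYRO,
            "both": cls.ACCEL_GYRO,
            "accel_gyro": cls.ACCEL_GYRO,
            "a+g": cls.ACCEL_GYRO,
        }
        if key not in aliases:
            raise ValueError(f"unknown sensor subset {s!r}")
        return aliases[key]
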