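"""Exception hierarchy for the hip-ultrasound analysis pipeline."""


class HipsonoError(Exception):
    """Base class for all package-specific errors."""


class NoApexSignal(HipsonoError):
    """The heatmap carries no usable apex peak (flat or empty response)."""


class InsufficientRidgeSupport(HipsonoError):
    """Too few local-maximum points survive selection to fit the ilium ridge."""


class RoofNotFound(HipsonoError):
    """No local maximum inside the acetabular-roof search rectangle."""


class InsufficientRoofSupport(HipsonoError):
    """Fewer than two roof points survive the sector selection."""


class ManifestSchemaError(HipsonoError):
    """A manifest file is missing required columns or is malformed."""
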