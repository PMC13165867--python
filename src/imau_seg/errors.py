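"""Package-level exception types."""


class ConfigurationError(ValueError):
    """A config object violates one of its invariants; the message names the field."""


class PretrainedWeightsUnavailable(RuntimeError):
    """ImageNet backbone weights were requested but no weight file is available.

    The models are fully usable with seeded random initialization
    (``pretrained_backbone=False``), which is how every test and experiment
    in this repository runs.
    """


class DatasetError(ValueError):
    """A dataset directory or manifest is malformed (orphans, missing files, empty)."""
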