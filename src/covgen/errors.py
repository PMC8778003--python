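"""Exception hierarchy for covgen."""


class CovgenError(Exception):
    """Base class for all covgen errors."""


class InvalidStructureError(CovgenError):
    """A SMILES/SDF record could not be parsed into a valid molecule."""

    def __init__(self, smiles: str, detail: str = "could not be parsed"):
        self.smiles = smiles
        super().__init__(f"invalid structure {smiles!r}: {detail}")


class AttachmentGrammarError(CovgenError):
    """A fragment violates the attachment-point grammar of its role."""


class RoleError(CovgenError):
    """A fragment with the wrong role was passed to a role-specific operation."""


class VocabularyError(CovgenError):
    """A sequence contains tokens outside the model vocabulary."""

    def __init__(self, tokens, detail: str = "out-of-vocabulary tokens"):
        self.tokens = list(tokens)
        super().__init__(f"{detail}: {sorted(set(self.tokens))}")


class AssemblyError(CovgenError):
    """Fragment re-assembly produced an inconsistent molecule."""


class ConformerError(CovgenError):
    """3D embedding failed for all attempts."""


class ConfigError(CovgenError):
    """A run configuration is inconsistent or references missing files."""


class StageError(CovgenError):
    """A pipeline stage yielded zero survivors; carries the partial manifest."""

    def __init__(self, stage: str, manifest=None):
        self.stage = stage
        self.manifest = manifest
        super().__init__(f"stage {stage!r} yielded zero survivors")


class DegenerateInputError(CovgenError):
    """Input carries no variance / no usable information for the operation."""
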