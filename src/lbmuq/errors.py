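"""Exception hierarchy shared across the package."""


class LbmuqError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(LbmuqError, ValueError):
    """Invalid or inconsistent voxel geometry (unresolvable lumen, bad links...)."""


class StabilityError(LbmuqError, ValueError):
    """A requested state violates a lattice stability precondition (Ma >= 1 etc.)."""


class SimulationDiverged(LbmuqError, RuntimeError):
    """The solver produced non-physical densities; carries the step and site."""

    def __init__(self, step: int, site: int, detail: str = ""):
        self.step = step
        self.site = site
        msg = f"simulation diverged at step {step}, site {site}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class UQError(LbmuqError, ValueError):
    """Invalid inputs to the uncertainty-quantification engine."""


class CampaignError(LbmuqError, RuntimeError):
    """Campaign orchestration failure (diverged node, bad preset, bad config)."""
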