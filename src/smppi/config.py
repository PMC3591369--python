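"""Run configuration: the method's cutoffs and classifier settings.

Defaults are the method's standard operating point — a bare run applies
the method as described: 5 Å interface and contact cutoffs, 10 Å
protrusion sphere, 110° patch angle bound, 40% sequence-identity
threshold, at least 2 shared overlap residues, and a 5-of-7 patch vote.
Config files are flat ``key = value`` text; command-line flags override
file values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields


@dataclass
class RunConfig:
    interface_cutoff: float = 5.0      # Å, residue-to-partner heavy-atom distance
    contact_cutoff: float = 5.0        # Å, contact-density neighbourhood
    sphere_radius: float = 10.0        # Å, protrusion sphere
    patch_angle_max: float = 110.0     # degrees, solvent-vector bound
    min_identity: float = 0.40         # reference-protein sequence identity
    min_overlap: int = 2               # shared interface residues per pair
    min_votes: int = 5                 # predicted-O members of a size-7 patch
    surface_threshold: float = 0.05    # relative SASA for surface residues
    probe_radius: float = 1.4          # Å, SASA probe
    sasa_points: int = 960             # sphere sample points per atom
    grid_spacing: float = 0.5          # Å, protrusion volume grid
    n_trees: int = 500                 # trees per forest member
    K: int = 1000                      # balanced down-sampling draws
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("interface_cutoff", "contact_cutoff", "sphere_radius",
                     "patch_angle_max", "surface_threshold", "probe_radius",
                     "grid_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(text: str, base: RunConfig | None = None) -> RunConfig:
    """Parse flat ``key = value`` config text over the defaults."""
    values = asdict(base) if base is not None else asdict(RunConfig())
    types = {f.name: f.type for f in fields(RunConfig)}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected 'key = value'")
        key, _, raw = (part.strip() for part in line.partition("="))
        if key not in values:
            raise ValueError(f"config line {lineno}: unknown key {key!r}")
        current = values[key]
        if isinstance(current, bool):
            values[key] = raw.lower() in ("1", "true", "yes")
        elif isinstance(current, int):
            values[key] = int(raw)
        elif isinstance(current, float):
            values[key] = float(raw)
        else:
            values[key] = raw
    return RunConfig(**values)
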