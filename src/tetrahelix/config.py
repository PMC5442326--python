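"""Runtime configuration shared across analysis stages.

All tunable thresholds live in a single flat :class:`Config` dataclass so
that every report can record a reproducible hash of the parameters that
produced it.  Configs round-trip through a flat ``key=value`` text format.
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class Config:
    # --- sequence scanning -------------------------------------------------
    #: spacer bounds for the AGCGA consensus (four AGCGA repeats, N_1-20)
    agcga_min_spacer: int = 1
    agcga_max_spacer: int = 20
    #: spacer bounds for the G4 consensus (four GGG tracts, N_1-7)
    g4_min_spacer: int = 1
    g4_max_spacer: int = 7
    both_strands: bool = True
    report: str = "minimal"  # or "all"

    # --- hydrogen-bond detection ------------------------------------------
    hbond_d_max: float = 3.5      # donor-acceptor heavy-atom cutoff, A
    hbond_theta_min: float = 120.0  # donor-H...acceptor angle minimum, deg
    hbond_base_only: bool = True

    # --- pairing / quartets -------------------------------------------------
    #: fraction of models a pair/quartet must appear in to enter the consensus
    consensus_fraction: float = 0.5
    #: minimum inter-pair twist for a crisscross call, deg
    crisscross_twist_min: float = 35.0
    #: maximum inter-pair rise for two pairs to count as stacked, A
    stack_rise_max: float = 6.0

    # --- grooves ------------------------------------------------------------
    groove_pp_offset: float = 5.8  # subtracted from P-P distances, A
    groove_narrow: float = 4.0     # width < narrow  -> "narrow"
    groove_wide: float = 9.0       # width > wide    -> "wide"

    # --- NOE restraints -----------------------------------------------------
    noe_reference_distance: float = 3.9   # A, calibration target
    noe_cutoff_strong: float = 3.0        # r-hat class cutoffs, A
    noe_cutoff_medium: float = 4.2
    noe_cutoff_weak: float = 5.5
    distance_force_constant: float = 20.0   # kcal/mol/A^2
    torsion_force_constant: float = 200.0   # kcal/mol/rad^2
    planarity_force_constant: float = 50.0  # kcal/mol/rad^2

    # --- topology calls -----------------------------------------------------
    type1_min_gaga: int = 2
    type1_min_gcgc: int = 1
    type2_min_gc_pairs: int = 4

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        cfg = cls()
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise KeyError(f"{path}:{lineno}: unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.lower() in ("1", "true", "yes", "on"))
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            else:
                setattr(cfg, key, value)
        return cfg

    def hash(self) -> str:
        """Stable short hash of all parameter values."""
        text = ";".join(
            f"{f.name}={getattr(self, f.name)!r}" for f in dataclasses.fields(self)
        )
        return hashlib.sha256(text.encode()).hexdigest()[:12]


DEFAULT_CONFIG = Config()
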