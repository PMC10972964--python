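"""Scanner configuration: every tunable window in one place.

Values can be overridden from a ``key=value`` text file (one pair per line,
``#`` comments allowed).  Amino-acid windows are 1-based inclusive positions
within the translated V exon, bracketing typical V-domain geometry; they are
deliberately generous because real V exons vary in leader length and loop
size.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["ScanConfig"]


@dataclass
class ScanConfig:
    # V exon (leader-inclusive for single-exon genes) length window, nt
    v_exon_min: int = 240
    v_exon_max: int = 360
    # 1st-CYS searched at these aa positions of the V exon translation
    first_cys_start: int = 15
    first_cys_end: int = 40
    # CONSERVED-TRP this many aa after the accepted 1st-CYS
    trp_min_after_cys: int = 10
    trp_max_after_cys: int = 20
    # 2nd-CYS motif (YYC/YFC/YLC/YHC/YIC/TFC) start position window
    second_cys_start: int = 80
    second_cys_end: int = 115
    # J gene span (RSS end to splice donor), nt
    j_len_min: int = 40
    j_len_max: int = 75
    # D segment length bounds, nt
    d_len_min: int = 8
    d_len_max: int = 25
    # RSS geometry: spacer classes with +/- tolerance; nonamer located by a
    # degenerate consensus so spacer-length discrimination is well defined
    v_spacer_class: int = 23
    j_spacer_class: int = 12
    spacer_tolerance: int = 1
    heptamer_prefix: str = "CAC"
    nonamer_pattern: str = "NCAAAANNN"
    # family motif must occur within this many aa of the mature V start
    family_motif_window: int = 15
    # for single-exon candidates the cleavage site is unknown offline: allow
    # the family motif this many extra aa to cover the uncleaved leader
    single_exon_leader_aa: int = 25
    # treat the secondary J motif TNNBNRT as required between the J core
    # motif and the splice donor; relaxing demotes it to a warning note
    relax_j_secondary: bool = False
    # optional threshold for an external RSS scorer hook
    rss_score_threshold: float | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "ScanConfig":
        cfg = cls()
        types = {f.name: f.type for f in fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if not hasattr(cfg, key):
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.lower() in ("1", "true", "yes", "on"))
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float) or current is None and "threshold" in key:
                setattr(cfg, key, float(value))
            else:
                setattr(cfg, key, value)
        return cfg

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name}={getattr(self, f.name)}" for f in fields(self)
                 if getattr(self, f.name) is not None]
        Path(path).write_text("\n".join(lines) + "\n")

    def spacer_lengths(self, spacer_class: int) -> range:
        return range(spacer_class - self.spacer_tolerance,
                     spacer_class + self.spacer_tolerance + 1)
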