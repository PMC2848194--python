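"""Edge-list and provenance IO.

Networks travel as TSV with columns (regulator, target, weight, sign),
rows sorted lexicographically by (regulator, target); comment lines start
with '#' and carry provenance (tool version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

NETWORK_COLUMNS = ("regulator", "target", "weight", "sign")


class NetworkFormatError(ValueError):
    pass


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(seed: int | None = None, config=None) -> list[str]:
    from . import __version__

    lines = [f"# tanhgrn {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config: {config_hash(config)}")
    return lines


def write_network(
    path: str | Path,
    edges,
    seed: int | None = None,
    config=None,
) -> None:
    """Write a (regulator, target, weight, sign) edge list as TSV."""
    path = Path(path)
    rows = sorted(
        ((e[0], e[1], float(e[2]), int(e[3])) for e in edges),
        key=lambda r: (r[0], r[1]),
    )
    with path.open("w") as fh:
        for line in provenance_lines(seed, config):
            fh.write(line + "\n")
        fh.write("\t".join(NETWORK_COLUMNS) + "\n")
        for reg, tgt, w, s in rows:
            fh.write(f"{reg}\t{tgt}\t{w!r}\t{s}\n")


def read_network(path: str | Path) -> list[tuple[str, str, float, int]]:
    """Read an edge-list TSV written by :func:`write_network`."""
    path = Path(path)
    edges = []
    with path.open() as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = tuple(parts)
                if header != NETWORK_COLUMNS:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: unknown columns {header!r}, "
                        f"expected {NETWORK_COLUMNS!r}"
                    )
                continue
            if len(parts) != 4:
                raise NetworkFormatError(f"{path}:{lineno}: expected 4 columns")
            reg, tgt, w, s = parts
            edges.append((reg, tgt, float(w), int(s)))
    if header is None:
        raise NetworkFormatError(f"{path}: empty file (no header)")
    return edges
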