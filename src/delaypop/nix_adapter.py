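"""Optional adapter for the deposited electrophysiology archive.

The recordings behind the original study are deposited in NIX format
(DOI 10.12751/g-node.78xqwl).  This adapter converts such an archive
into the package's plain-text study layout (``stimulus.csv``,
``cells.json``, ``spikes/<cell>/<trial>.csv``) so that the analysis
pipeline runs identically on recorded and synthetic data.  It imports
``nixio`` lazily: the core package never requires it, and all tests run
on synthetic data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["convert_nix_directory"]


def _require_nixio():
    try:
        import nixio
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading NIX archives requires the optional 'nixio' package "
            "(pip install nixio); the rest of delaypop works without it"
        ) from exc
    return nixio


def convert_nix_directory(
    nix_dir: str | Path,
    out_dir: str | Path,
    spike_tag: str = "Spikes",
    stimulus_tag: str = "GlobalEFieldStimulus",
) -> list[str]:
    """Convert a directory of ``.nix`` recordings into a study directory.

    Each ``.nix`` file becomes one cell; spike-time data arrays matching
    ``spike_tag`` become trial CSVs and the first stimulus trace matching
    ``stimulus_tag`` becomes ``stimulus.csv``.  Returns the converted
    cell ids.  This routine covers the generic NIX layout (blocks with
    data arrays of spike times in seconds); project-specific metadata
    beyond spike times and stimuli is not interpreted.
    """
    nixio = _require_nixio()
    nix_dir, out_dir = Path(nix_dir), Path(out_dir)
    files = sorted(nix_dir.glob("*.nix"))
    if not files:
        raise FileNotFoundError(f"no .nix files under {nix_dir}")
    converted = []
    for path in files:
        cell_id = path.stem
        cdir = out_dir / "spikes" / cell_id
        cdir.mkdir(parents=True, exist_ok=True)
        nf = nixio.File.open(str(path), nixio.FileMode.ReadOnly)
        try:
            trial = 0
            for block in nf.blocks:
                for da in block.data_arrays:
                    name = da.name or ""
                    if spike_tag.lower() in name.lower():
                        times = np.asarray(da[:], dtype=float)
                        np.savetxt(
                            cdir / f"trial{trial:03d}.csv", np.sort(times),
                            fmt="%.9g",
                            header=f"duration={times.max() if times.size else 0.0}",
                        )
                        trial += 1
                    elif stimulus_tag.lower() in name.lower() and not (
                        out_dir / "stimulus.csv"
                    ).exists():
                        vals = np.asarray(da[:], dtype=float)
                        dim = da.dimensions[0]
                        dt = getattr(dim, "sampling_interval", None)
                        if dt:
                            t = np.arange(vals.size) * float(dt)
                            out_dir.mkdir(parents=True, exist_ok=True)
                            with open(out_dir / "stimulus.csv", "w") as fh:
                                fh.write("time,value\n")
                                for ti, vi in zip(t, vals):
                                    fh.write(f"{ti:.9g},{vi:.9g}\n")
        finally:
            nf.close()
        converted.append(cell_id)
    return converted
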