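#!/usr/bin/env python
"""Clean the raw trajectories and rasterise them into activity intensity.

Applies the three quality-control rules (five-minute duration cut,
activity-specific speed bands, 30 m/s teleport limit) and converts the
surviving tracks into per-unit cumulative activity time per square
kilometre for hiking, jogging and cycling.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "corridor"

from corridorpa import io as cio
from corridorpa.trajectories import activity_intensity, clean_trajectories


def main() -> None:
    grid = cio.read_grid(OUT / "grid.geojson", OUT / "factors.csv")
    points = cio.read_trajectories(OUT / "trajectories.csv")
    clean, report = clean_trajectories(points)
    cio.write_trajectories(clean, OUT / "trajectories_clean.csv")
    (OUT / "cleaning_report.txt").write_text(report.to_text())
    intensity = activity_intensity(clean, grid)
    long = intensity.reset_index().melt(id_vars="unit_id",
                                        var_name="activity",
                                        value_name="intensity")
    long.to_csv(OUT / "intensity.csv", index=False, float_format="%.9g")
    print(report.to_text().strip())
    print("mean intensity (s/km^2):",
          {a: round(float(intensity[a].mean()), 1) for a in intensity})


if __name__ == "__main__":
    main()
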