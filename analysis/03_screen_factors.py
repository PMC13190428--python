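#!/usr/bin/env python
"""Screen the 34 candidate factors for multicollinearity.

Pearson correlations above 0.8 are resolved with PCA loadings (the
weaker-loading member of each pair is excluded) and the survivors
receive variance-contribution weights for the weighted spatial
clustering stage.
"""

from collections import Counter
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "corridor"

from corridorpa import io as cio
from corridorpa.screening import pca_screen


def main() -> None:
    grid = cio.read_grid(OUT / "grid.geojson", OUT / "factors.csv")
    res = pca_screen(grid.factors, grid.dimension_of)
    res.to_frame(grid.dimension_of).to_csv(OUT / "screening.csv",
                                           index=False, float_format="%.9g")
    split = Counter(grid.dimension_of[f] for f in res.retained)
    print(f"retained {len(res.retained)} of {grid.factors.shape[1]} factors")
    print("per dimension:", dict(split))
    print("excluded:", {f: f"|r|={r:.2f} vs {p}" for f, (p, r)
                        in sorted(res.excluded.items())})


if __name__ == "__main__":
    main()
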