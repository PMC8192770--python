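"""Storage-density and sequencing-cost tradeoffs of Preview encoding.

Preview encoding stores the full-file (higher-HD) strands at an elevated copy
ratio ``c`` relative to the preview strands to compensate for their lower PCR
efficiency, so a file whose preview fraction is ``f`` occupies

    D(f, c) = f * 1 + (1 - f) * c

physical copies per unique strand relative to single-copy normal encoding.
Searching an ``n``-file library, previewing costs ``f`` of a full-file
sequencing run per file; after the target is found its full file is
sequenced once, so relative to sequencing full files the preview strategy
costs ``n*f + 1`` versus ``n`` (search-all), and the savings grow as the
preview fraction shrinks or the library grows.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["density_ratio", "cost_to_find", "PreviewEconomics", "sweep"]


def density_ratio(f: float, c: float, model: str = "total") -> float:
    """Stored physical copies per unique strand, relative to normal encoding.

    ``model="total"`` counts preview and full-file copies
    (``D = f + (1-f)*c``); ``model="fullonly"`` counts only the boosted
    full-file strands (``D = (1-f)*c``), the variant implied by some printed
    roundings.
    """
    if not 0 < f <= 1:
        raise ValueError("preview fraction f must be in (0, 1]")
    if c < 1:
        raise ValueError("copy ratio c must be >= 1")
    if model == "total":
        return f + (1.0 - f) * c
    if model == "fullonly":
        return (1.0 - f) * c
    raise ValueError("model must be 'total' or 'fullonly'")


def cost_to_find(
    n_files: int,
    f: float,
    search_all: bool = True,
    full_access_overhead: float = 1.0,
) -> tuple[float, float, float]:
    """Sequencing cost of finding one file, in full-file-sequencing units.

    Returns ``(cost_preview, cost_normal, savings)``. ``search_all`` previews
    every file before sequencing the target in full (worst case); otherwise
    the expected search position ``(n+1)/2`` is used for both strategies.
    ``full_access_overhead`` scales the final full-file sequencing step (e.g.
    to fold in empirically uneven read distributions).
    """
    if n_files < 1:
        raise ValueError("n_files must be >= 1")
    if not 0 < f < 1:
        raise ValueError("preview fraction f must be in (0, 1) for a preview search")
    if full_access_overhead <= 0:
        raise ValueError("full_access_overhead must be positive")
    searched = float(n_files) if search_all else (n_files + 1) / 2.0
    cost_preview = searched * f + 1.0 * full_access_overhead
    cost_normal = searched
    savings = 1.0 - cost_preview / cost_normal
    return cost_preview, cost_normal, savings


@dataclass(frozen=True)
class PreviewEconomics:
    """Density and cost summary for one (f, c, n_files) configuration."""

    f: float
    c: float
    n_files: int
    density_model: str = "total"
    search_all: bool = True

    @property
    def density(self) -> float:
        return density_ratio(self.f, self.c, self.density_model)

    @property
    def cost_preview(self) -> float:
        return cost_to_find(self.n_files, self.f, self.search_all)[0]

    @property
    def cost_normal(self) -> float:
        return cost_to_find(self.n_files, self.f, self.search_all)[1]

    @property
    def savings(self) -> float:
        return cost_to_find(self.n_files, self.f, self.search_all)[2]


def sweep(
    fractions: list[float],
    copy_ratios: list[float],
    n_files: int = 15,
    density_model: str = "total",
) -> list[dict]:
    """Grid of density and cost figures over preview fractions and copy ratios."""
    rows = []
    for c in copy_ratios:
        for f in fractions:
            cost_p, cost_n, sav = cost_to_find(n_files, f)
            rows.append(
                {
                    "f": f,
                    "c": c,
                    "n_files": n_files,
                    "density_ratio": density_ratio(f, c, density_model),
                    "cost_preview": cost_p,
                    "cost_normal": cost_n,
                    "savings": sav,
                }
            )
    return rows
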