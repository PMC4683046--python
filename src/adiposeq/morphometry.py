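"""Adipocyte sizing: spherical volumes, depot cellularity, size distributions.

Adipocytes are modelled as spheres of lipid.  A cell of diameter d µm has
volume (π/6)·d³ µm³ = (π/6)·d³/1000 pl; at a lipid density ρ (ng/pl, default
0.915) its mass is volume·ρ·10⁻⁹ g.  The number of cells in a depot is the
depot mass divided by the *mean per-cell mass* — the mean of each cell's own
mass, not the mass of a cell at the mean diameter (d³ is convex, so the two
differ for any non-degenerate population).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .io_model import AdipocytePopulation

#: µm³ per picolitre.
UM3_PER_PL = 1e3


def cell_volume_pl(diameter_um: float) -> float:
    """Spherical cell volume in picolitres from a diameter in µm."""
    d = np.asarray(diameter_um, dtype=float)
    if (d <= 0).any():
        raise ValueError("diameter must be positive")
    out = (np.pi / 6.0) * d**3 / UM3_PER_PL
    return float(out) if out.ndim == 0 else out


def mean_cell_mass_g(pop: AdipocytePopulation) -> float:
    """Mean per-cell lipid mass in grams (average of per-cell masses)."""
    if pop.diameters_um.size == 0:
        raise ValueError("population has no measured diameters")
    volumes = cell_volume_pl(pop.diameters_um)
    return float(np.mean(volumes) * pop.lipid_density_ng_per_pl * 1e-9)


def depot_cellularity(pop: AdipocytePopulation) -> float:
    """Estimated number of adipocytes in the depot: mass / mean cell mass."""
    m = mean_cell_mass_g(pop)
    if m == 0:
        raise ValueError("mean cell mass is zero")
    return pop.depot_mass_g / m


def bin_distribution(diameters_um, bin_width_um: float = 10.0) -> dict[float, float]:
    """Percent of cells per left-closed diameter bin anchored at 0.

    Returns {bin_start: percent}; only occupied-range bins up to the largest
    diameter appear, and the percentages sum to 100.
    """
    d = np.asarray(diameters_um, dtype=float)
    if d.size == 0:
        raise ValueError("no diameters to bin")
    if (d <= 0).any():
        raise ValueError("diameters must be positive")
    n_bins = int(np.floor(d.max() / bin_width_um)) + 1
    edges = np.arange(0, (n_bins + 1) * bin_width_um, bin_width_um)
    counts, _ = np.histogram(d, bins=edges)
    pct = 100.0 * counts / d.size
    return {float(edges[i]): float(pct[i]) for i in range(n_bins)}


def compare_distributions(
    pops_a: list[AdipocytePopulation],
    pops_b: list[AdipocytePopulation],
    bin_width_um: float = 10.0,
) -> dict[float, float]:
    """Per-bin two-sample t-test on per-animal bin percentages.

    Each animal contributes one percentage per bin (0 when none of its cells
    fall there); bins empty in every animal of both groups are omitted.
    Degenerate bins (zero variance in both groups) follow the p = 1 / p = 0
    equal/unequal-mean convention.
    """
    if len(pops_a) < 2 or len(pops_b) < 2:
        raise ValueError("need at least 2 animals per group")
    per_animal_a = [bin_distribution(p.diameters_um, bin_width_um) for p in pops_a]
    per_animal_b = [bin_distribution(p.diameters_um, bin_width_um) for p in pops_b]
    bins = sorted(set().union(*per_animal_a, *per_animal_b))
    out: dict[float, float] = {}
    for b in bins:
        a_vals = np.array([d.get(b, 0.0) for d in per_animal_a])
        b_vals = np.array([d.get(b, 0.0) for d in per_animal_b])
        if not a_vals.any() and not b_vals.any():
            continue  # bin absent in all animals
        if np.var(a_vals) == 0 and np.var(b_vals) == 0:
            out[b] = 1.0 if a_vals.mean() == b_vals.mean() else 0.0
        else:
            out[b] = float(stats.ttest_ind(a_vals, b_vals, equal_var=True).pvalue)
    return out


def summarize_population(pop: AdipocytePopulation) -> dict[str, float]:
    """Mean diameter, mean cell mass, and cellularity for one population."""
    return {
        "mean_diameter_um": float(np.mean(pop.diameters_um)),
        "mean_cell_mass_g": mean_cell_mass_g(pop),
        "cellularity": depot_cellularity(pop),
    }
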