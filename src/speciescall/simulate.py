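"""Accuracy studies for a species-seq panel, plus toy-panel generation.

Two simulation studies quantify how the scoring system degrades:

* **Missing-data study** -- for each species, expected homozygous profiles
  with ``k`` randomly chosen species-informative loci omitted, for every
  ``k`` from 1 to the species' informative-locus count, a fixed number of
  replicates each.  Measures how ambiguity (extra candidate species) and
  no-calls grow as genotyping success drops.
* **Shared-polymorphism study** -- expected profiles in which ``k`` randomly
  chosen informative loci segregate: at each affected locus the two alleles
  of the sample are drawn independently with alternative-allele probability
  ``p`` (Hardy-Weinberg genotype frequencies ``(1-p)^2 : 2p(1-p) : p^2``).
  Heterozygotes are inert to the scorer, so errors are driven by the ``p^2``
  chance of an alternative-allele homozygote.

Every simulated call is classified against the known truth into a four-way
outcome partition: exclusive-correct, true-included (truth plus alternatives),
true-excluded, or no-call.
"""

from __future__ import annotations

import enum
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import CallParams, SpeciesPanel, SpeciesSeqEntry
from .scoring import (
    STATE_HET,
    STATE_HOM1,
    STATE_HOM2,
    STATE_MISSING,
    PanelArrays,
    SpeciesCall,
)

__all__ = [
    "Outcome",
    "SimScenario",
    "SimulationResult",
    "classify_outcome",
    "expected_profile",
    "simulate_missing_study",
    "simulate_shared_poly_study",
    "run_shared_poly_grid",
    "missing_success_bins",
    "summarize",
    "bootstrap_mean_ci",
    "tp1_panel",
    "generate_toy_panel",
]

#: Affected-locus grid of the shared-polymorphism study.
DEFAULT_K_GRID = (1, 2, 5, 10, 15)
#: Alternative-allele frequency grid of the shared-polymorphism study.
DEFAULT_P_GRID = (0.01, 0.05, 0.1, 0.2)


class Outcome(enum.Enum):
    """Four-way partition of a simulated call against the known truth."""

    EXCLUSIVE_CORRECT = "exclusive_correct"
    TRUE_INCLUDED = "true_included"
    TRUE_EXCLUDED = "true_excluded"
    NO_CALL = "no_call"


@dataclass(frozen=True)
class SimScenario:
    """One simulated condition (bookkeeping record)."""

    study: str                 # "missing" | "shared_poly"
    species: str
    k: int                     # loci omitted / affected
    p: float | None            # alternative-allele frequency (shared_poly)
    reps: int
    seed: int


_COUNT_COLS = [
    "n_exclusive",
    "n_included",
    "n_excluded",
    "n_nocall",
    "n_included_one_alt",
]


class SimulationResult:
    """Per-scenario outcome tallies.

    ``scenarios`` has one row per (study, species, k, p) with outcome counts;
    counts of the four outcome classes sum to ``reps`` in every row.
    """

    def __init__(self, scenarios: pd.DataFrame):
        self.scenarios = scenarios.reset_index(drop=True)
        total = self.scenarios[
            ["n_exclusive", "n_included", "n_excluded", "n_nocall"]
        ].sum(axis=1)
        if not (total == self.scenarios["reps"]).all():
            raise ValueError("outcome counts do not sum to reps")

    def __len__(self) -> int:
        return len(self.scenarios)

    @property
    def total_calls(self) -> int:
        return int(self.scenarios["reps"].sum())

    def rates(self) -> pd.DataFrame:
        """Scenario table with outcome rates (per simulated genotype)."""
        frame = self.scenarios.copy()
        reps = frame["reps"]
        frame["exclusive_rate"] = frame["n_exclusive"] / reps
        frame["included_rate"] = frame["n_included"] / reps
        frame["excluded_rate"] = frame["n_excluded"] / reps
        frame["nocall_rate"] = frame["n_nocall"] / reps
        return frame

    @classmethod
    def concat(cls, results: Iterable["SimulationResult"]) -> "SimulationResult":
        frames = [r.scenarios for r in results]
        return cls(pd.concat(frames, ignore_index=True))


def classify_outcome(call: SpeciesCall, truth: str) -> Outcome:
    """Classify one call against the true species."""
    if not call.candidates:
        return Outcome.NO_CALL
    if truth not in call.candidates:
        return Outcome.TRUE_EXCLUDED
    if len(call.candidates) == 1:
        return Outcome.EXCLUSIVE_CORRECT
    return Outcome.TRUE_INCLUDED


def expected_profile(panel: SpeciesPanel, species: str) -> dict[str, str]:
    """Expected homozygous genotype at every informative locus of *species*
    (loci without an association are absent, i.e. missing)."""
    profile: dict[str, str] = {}
    for locus in panel.informative_loci(species):
        profile[locus] = panel.expected_genotype(species, locus)  # type: ignore[assignment]
    return profile


# -- internal vectorised machinery -----------------------------------------


def _scenario_rng(seed: int, study: str, species: str, k: int, p: float | None):
    """Independent stream per (study, species, scenario): results do not
    depend on which scenarios run, or in which order."""
    tokens = [
        int(seed),
        zlib.crc32(study.encode()),
        zlib.crc32(species.encode()),
        int(k),
        int(round((p or 0.0) * 10**6)),
    ]
    return np.random.default_rng(np.random.SeedSequence(tokens))


def _expected_states(arrays: PanelArrays, species: str) -> np.ndarray:
    states = np.full(len(arrays.locus_ids), STATE_MISSING, dtype=np.int8)
    for i, entry in enumerate(arrays.panel):
        if species in entry.assoc1:
            states[i] = STATE_HOM1
        elif species in entry.assoc2:
            states[i] = STATE_HOM2
    return states


def _informative_indices(arrays: PanelArrays, species: str) -> np.ndarray:
    return np.array(
        [i for i, e in enumerate(arrays.panel) if species in e.species],
        dtype=np.intp,
    )


def _tally(
    arrays: PanelArrays,
    states: np.ndarray,
    truth: str,
    params: CallParams,
) -> dict[str, int]:
    S, P, H, G, _ = arrays.score_states(states)
    cand, _ = arrays.call_batch(S, P, H, G, params)
    t = arrays.species.index(truth)
    n_cand = cand.sum(axis=1)
    true_in = cand[:, t]
    exclusive = true_in & (n_cand == 1)
    included = true_in & (n_cand > 1)
    excluded = (~true_in) & (n_cand >= 1)
    nocall = n_cand == 0
    return {
        "n_exclusive": int(exclusive.sum()),
        "n_included": int(included.sum()),
        "n_excluded": int(excluded.sum()),
        "n_nocall": int(nocall.sum()),
        "n_included_one_alt": int((included & (n_cand == 2)).sum()),
    }


def _random_subsets(
    rng: np.random.Generator, reps: int, pool: np.ndarray, k: int
) -> np.ndarray:
    """(reps x k) entry indices: an independent uniform k-subset of *pool*
    per replicate."""
    order = np.argsort(rng.random((reps, pool.size)), axis=1)[:, :k]
    return pool[order]


# -- the two studies --------------------------------------------------------


def simulate_missing_study(
    panel: SpeciesPanel | PanelArrays,
    species: str | Sequence[str] | None = None,
    reps: int = 1000,
    seed: int = 0,
    params: CallParams | None = None,
) -> SimulationResult:
    """Random genotype omission study.

    For each species and each omission level ``k`` in ``1..n_informative``,
    simulates *reps* expected profiles with a fresh uniform ``k``-subset of
    informative loci omitted per replicate, calls them with *params*
    (defaults), and tallies outcomes.  Emits ``n_informative * reps``
    simulated genotypes per species.
    """
    arrays = panel if isinstance(panel, PanelArrays) else PanelArrays(panel)
    params = params or CallParams()
    if species is None:
        species_list = list(arrays.species)
    elif isinstance(species, str):
        species_list = [species]
    else:
        species_list = list(species)

    rows = []
    for sp in species_list:
        base = _expected_states(arrays, sp)
        pool = _informative_indices(arrays, sp)
        n_inf = pool.size
        for k in range(1, n_inf + 1):
            rng = _scenario_rng(seed, "missing", sp, k, None)
            states = np.repeat(base[None, :], reps, axis=0)
            drop = _random_subsets(rng, reps, pool, k)
            states[np.arange(reps)[:, None], drop] = STATE_MISSING
            tallies = _tally(arrays, states, sp, params)
            rows.append(
                {
                    "study": "missing",
                    "species": sp,
                    "k": k,
                    "p": np.nan,
                    "success": (n_inf - k) / n_inf,
                    "reps": reps,
                    **tallies,
                }
            )
    return SimulationResult(pd.DataFrame(rows))


def simulate_shared_poly_study(
    panel: SpeciesPanel | PanelArrays,
    species: str,
    k: int,
    p: float,
    reps: int = 2000,
    seed: int = 0,
    params: CallParams | None = None,
) -> SimulationResult:
    """Shared-polymorphism study, one (species, k, p) scenario.

    Per replicate a fresh uniform ``k``-subset of the species' informative
    loci is affected; at each affected locus the genotype is drawn from two
    independent allele draws with alternative-allele probability ``p``
    (expected homozygote ``(1-p)^2``, heterozygote ``2p(1-p)``, alternative
    homozygote ``p^2``).  Unaffected loci keep their expected genotypes.
    """
    arrays = panel if isinstance(panel, PanelArrays) else PanelArrays(panel)
    params = params or CallParams()
    if species not in arrays.species:
        raise KeyError(f"unknown species code {species!r}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"alternative-allele frequency must lie in [0,1]: {p}")
    base = _expected_states(arrays, species)
    pool = _informative_indices(arrays, species)
    if not 1 <= k <= pool.size:
        raise ValueError(
            f"k={k} outside 1..{pool.size} informative loci for {species}"
        )
    rng = _scenario_rng(seed, "shared_poly", species, k, p)
    states = np.repeat(base[None, :], reps, axis=0)
    affected = _random_subsets(rng, reps, pool, k)
    alt_count = (rng.random((reps, k)) < p).astype(np.int8) + (
        rng.random((reps, k)) < p
    ).astype(np.int8)
    rows_idx = np.arange(reps)[:, None]
    expected = states[rows_idx, affected]
    flipped = np.where(expected == STATE_HOM1, STATE_HOM2, STATE_HOM1).astype(np.int8)
    drawn = np.where(
        alt_count == 0, expected, np.where(alt_count == 1, STATE_HET, flipped)
    ).astype(np.int8)
    states[rows_idx, affected] = drawn
    tallies = _tally(arrays, states, species, params)
    row = {
        "study": "shared_poly",
        "species": species,
        "k": k,
        "p": p,
        "success": 1.0,
        "reps": reps,
        **tallies,
    }
    return SimulationResult(pd.DataFrame([row]))


def run_shared_poly_grid(
    panel: SpeciesPanel | PanelArrays,
    species: str | Sequence[str] | None = None,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    reps: int = 2000,
    seed: int = 0,
    params: CallParams | None = None,
) -> SimulationResult:
    """Shared-polymorphism study over a (k, p) grid for one or all species.

    Grid values of ``k`` exceeding a species' informative-locus count are
    skipped (a species described by only 3 loci runs k = 1, 2 only).
    """
    arrays = panel if isinstance(panel, PanelArrays) else PanelArrays(panel)
    if species is None:
        species_list = list(arrays.species)
    elif isinstance(species, str):
        species_list = [species]
    else:
        species_list = list(species)
    parts = []
    for sp in species_list:
        n_inf = _informative_indices(arrays, sp).size
        for k in k_grid:
            if k > n_inf:
                continue
            for p in p_grid:
                parts.append(
                    simulate_shared_poly_study(
                        arrays, sp, k, p, reps=reps, seed=seed, params=params
                    )
                )
    return SimulationResult.concat(parts)


# -- summaries ---------------------------------------------------------------


def missing_success_bins(
    result: SimulationResult, bin_width_pct: float = 2.0
) -> pd.DataFrame:
    """Pool a missing-data study across species into genotyping-success bins.

    Success rate is per-species: (informative loci retained) / (informative
    loci), aggregated into ``bin_width_pct``-point bins (lower edge label).
    Reports outcome percentages both per simulated genotype and per species
    call (no-calls excluded from the denominator).
    """
    frame = result.scenarios
    frame = frame[frame["study"] == "missing"].copy()
    if frame.empty:
        raise ValueError("no missing-study scenarios in result")
    edges = np.floor(frame["success"] * 100.0 / bin_width_pct) * bin_width_pct
    frame["bin_lo"] = edges
    grouped = frame.groupby("bin_lo", as_index=False)[_COUNT_COLS + ["reps"]].sum()
    grouped["bin_hi"] = grouped["bin_lo"] + bin_width_pct
    calls = grouped["reps"] - grouped["n_nocall"]
    grouped["n_calls"] = calls
    grouped["included_pct_of_calls"] = np.where(
        calls > 0, 100.0 * grouped["n_included"] / np.maximum(calls, 1), 0.0
    )
    grouped["excluded_pct_of_calls"] = np.where(
        calls > 0, 100.0 * grouped["n_excluded"] / np.maximum(calls, 1), 0.0
    )
    grouped["included_pct_of_sims"] = 100.0 * grouped["n_included"] / grouped["reps"]
    grouped["nocall_pct_of_sims"] = 100.0 * grouped["n_nocall"] / grouped["reps"]
    return grouped


def bootstrap_mean_ci(
    counts: np.ndarray,
    reps: np.ndarray,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Cross-species mean rate with a bootstrap percentile CI.

    ``counts[i] / reps[i]`` is the observed outcome rate for species *i*;
    replicates within a scenario are exchangeable Bernoulli draws, so the
    bootstrap resamples each species' replicate set parametrically and
    averages across species.
    """
    counts = np.asarray(counts, dtype=float)
    reps = np.asarray(reps, dtype=float)
    rates = counts / reps
    point = float(rates.mean())
    rng = np.random.default_rng(seed)
    draws = rng.binomial(
        reps.astype(int)[None, :].repeat(n_boot, axis=0),
        np.clip(rates, 0.0, 1.0)[None, :].repeat(n_boot, axis=0),
    ) / reps[None, :]
    means = draws.mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return point, float(lo), float(hi)


def summarize(
    results: SimulationResult | Iterable[SimulationResult],
    exclude: Sequence[str] = (),
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-species mean outcome rates per scenario with bootstrap CIs.

    Species in *exclude* are dropped (e.g. a species with too few loci to
    run the full grid).  Returns one row per (study, k, p) with, for each
    outcome class, the cross-species mean rate and percentile CI bounds.
    """
    if isinstance(results, SimulationResult):
        result = results
    else:
        result = SimulationResult.concat(results)
    frame = result.scenarios
    frame = frame[~frame["species"].isin(set(exclude))]
    rows = []
    for (study, k, p), group in frame.groupby(["study", "k", "p"], dropna=False):
        row: dict[str, object] = {"study": study, "k": k, "p": p}
        row["n_species"] = group["species"].nunique()
        row["reps_per_species"] = int(group["reps"].iloc[0])
        for label, col in (
            ("exclusive", "n_exclusive"),
            ("included", "n_included"),
            ("excluded", "n_excluded"),
            ("nocall", "n_nocall"),
        ):
            point, lo, hi = bootstrap_mean_ci(
                group[col].to_numpy(),
                group["reps"].to_numpy(),
                n_boot=n_boot,
                ci=ci,
                seed=seed,
            )
            row[f"{label}_rate"] = point
            row[f"{label}_lo"] = lo
            row[f"{label}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


# -- toy panels --------------------------------------------------------------


def tp1_panel() -> SpeciesPanel:
    """The fixed three-species, four-locus toy panel used throughout the
    tests and examples.

    ======  =======  =======  ========  ========  ======
    locus   allele1  allele2  assoc1    assoc2    weight
    ======  =======  =======  ========  ========  ======
    L1      A        G        X         Y,Z       2
    L2      C        T        X,Y       Z         1
    L3      G        T        Y         X,Z       2
    L4      A        C        Z         X,Y       2
    ======  =======  =======  ========  ========  ======

    Every species has absolute maximum score 7.
    """
    f = frozenset
    return SpeciesPanel(
        [
            SpeciesSeqEntry("L1", "A", "G", f({"X"}), f({"Y", "Z"}), 2.0),
            SpeciesSeqEntry("L2", "C", "T", f({"X", "Y"}), f({"Z"}), 1.0),
            SpeciesSeqEntry("L3", "G", "T", f({"Y"}), f({"X", "Z"}), 2.0),
            SpeciesSeqEntry("L4", "A", "C", f({"Z"}), f({"X", "Y"}), 2.0),
        ]
    )


def generate_toy_panel(
    n_species: int = 3,
    n_loci: int = 4,
    diag_fraction: float = 0.5,
    seed: int = 0,
) -> SpeciesPanel:
    """Random toy panel: every species informative at every locus.

    ``round(n_loci * diag_fraction)`` loci are single-species diagnostic
    (weight 2); the rest carry a random bipartition of all species (weight
    1).  Deterministic per seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if n_loci < 1:
        raise ValueError("need at least 1 locus")
    rng = np.random.default_rng(seed)
    names = ["X", "Y", "Z"] + [f"SP{i}" for i in range(4, n_species + 1)]
    species = names[:n_species]
    n_diag = int(round(n_loci * diag_fraction))
    diag_loci = set(rng.choice(n_loci, size=n_diag, replace=False).tolist())
    nucs = ("A", "C", "G", "T")
    entries = []
    for i in range(n_loci):
        a_idx, b_idx = rng.choice(4, size=2, replace=False)
        a1, a2 = nucs[a_idx], nucs[b_idx]
        if i in diag_loci:
            d = species[int(rng.integers(n_species))]
            assoc1 = frozenset({d})
            assoc2 = frozenset(s for s in species if s != d)
            weight = 2.0
        else:
            while True:
                mask = rng.random(n_species) < 0.5
                if 0 < mask.sum() < n_species:
                    break
            assoc1 = frozenset(s for s, m in zip(species, mask) if m)
            assoc2 = frozenset(s for s, m in zip(species, mask) if not m)
            weight = 1.0
        entries.append(SpeciesSeqEntry(f"L{i + 1}", a1, a2, assoc1, assoc2, weight))
    return SpeciesPanel(entries)
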