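"""Quantifying how well normal modes capture unbound→bound transitions.

Two complementary measures are provided. The *overlap* O_j of mode j with a
transition vector T is the absolute cosine between the two vectors restricted
to an atom subset:

    O_j = |Σ_i a_ij T_i| / (sqrt(Σ a_ij²) · sqrt(Σ T_i²))

where the sums run over the 3n' coordinates of the subset. A linear
combination of m modes is fitted by least squares, minimising the sum of
squared residuals S = ‖T − M β‖² over the subset rows; the normal-equation
solution β = (MᵀM)⁻¹MᵀT is computed via a rank-revealing least-squares
factorisation (identical at full rank, stable otherwise).

On atom subsets such as the binding interface the restricted mode vectors are
no longer orthogonal, which is exactly why the least-squares route is needed
rather than independent per-mode projections.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .enm import EnmParams, ModeSet, compute_modes
from .structure import (AtomSubset, Correspondence, Structure, find_interface,
                        kabsch, map_correspondence, read_structure, rmsd,
                        select_subset)
from .structure import superpose as superpose_coords

logger = logging.getLogger(__name__)


@dataclass
class Transition:
    """Paired unbound/bound coordinates for a conformational change.

    atom_indices index into the *unbound* structure (whose modes are used);
    unbound_coords/bound_coords are the paired coordinates in that order.
    """

    atom_indices: np.ndarray      # (k,) unbound atom indices, sorted
    unbound_coords: np.ndarray    # (k, 3)
    bound_coords: np.ndarray      # (k, 3)

    @property
    def displacement(self) -> np.ndarray:
        return self.bound_coords - self.unbound_coords


def make_transition(unbound: Structure, bound: Structure,
                    correspondence: Correspondence | None = None,
                    superpose: bool = False) -> Transition:
    """Build a transition from two structures, aligning them if needed.

    With ``superpose``, the unbound coordinates are rigidly superposed onto
    the bound ones over all paired atoms first — appropriate when the two
    structures come from crystals in unrelated frames, so that the overlap
    measures internal deformation rather than frame rotation.
    """
    if correspondence is None:
        correspondence = map_correspondence(unbound, bound)
    if len(correspondence.pairs) == 0:
        raise ValueError("no atom correspondence between the two structures")
    order = np.argsort(correspondence.pairs[:, 0])
    pairs = correspondence.pairs[order]
    d = unbound.coords[pairs[:, 0]]
    e = bound.coords[pairs[:, 1]]
    if superpose:
        d = superpose_coords(d, e)
    return Transition(atom_indices=pairs[:, 0],
                      unbound_coords=d, bound_coords=e)


@dataclass
class OverlapResult:
    overlaps: np.ndarray          # per-mode overlap, modes 1..n_considered
    max_overlap: float
    argmax_mode: int              # 1-based; ties -> lower mode number
    n_modes_considered: int


@dataclass
class FitResult:
    coefficients: np.ndarray      # β, Å (deformation magnitude per mode)
    residual: np.ndarray          # T_subset - M_subset β
    sum_sq: float                 # S, Å²
    fitted_coords: np.ndarray     # (n, 3) deformation applied to ALL atoms
    initial_rmsd: float
    fitted_rmsd: float
    percent_reduction: float
    mode_basis: np.ndarray        # M restricted to subset rows
    superposed: bool


def _restrict(t: Transition, subset: AtomSubset | None):
    """Intersect the transition's paired atoms with a subset selection."""
    if subset is None:
        local = np.arange(len(t.atom_indices))
    else:
        mask = np.isin(t.atom_indices, subset.indices)
        local = np.where(mask)[0]
    if len(local) == 0:
        raise ValueError("subset leaves no paired atoms")
    return local


def _mode_rows(atom_indices: np.ndarray) -> np.ndarray:
    return (3 * atom_indices[:, None] + np.arange(3)).reshape(-1)


def overlap(mode_vector: np.ndarray, t: Transition,
            subset: AtomSubset | None = None) -> float:
    """Absolute cosine between one mode and the transition on a subset."""
    local = _restrict(t, subset)
    rows = _mode_rows(t.atom_indices[local])
    a = np.asarray(mode_vector, float)[rows]
    d = t.displacement[local].reshape(-1)
    na, nd = np.linalg.norm(a), np.linalg.norm(d)
    if nd == 0.0:
        raise ValueError("transition vanishes on the subset; overlap undefined")
    if na == 0.0:
        raise ValueError("mode vanishes on the subset; overlap undefined")
    return float(abs(a @ d) / (na * nd))


def max_overlap(modes: ModeSet, t: Transition, subset: AtomSubset | None = None,
                n_consider: int = 20) -> OverlapResult:
    """Greatest overlap among the first ``n_consider`` modes (default 20)."""
    if modes.n_modes < n_consider:
        raise ValueError(
            f"mode set has {modes.n_modes} modes, {n_consider} requested")
    ovl = np.array([overlap(modes.mode(j), t, subset)
                    for j in range(1, n_consider + 1)])
    best = int(np.argmax(ovl))  # argmax takes the first maximum: lower mode wins ties
    return OverlapResult(overlaps=ovl, max_overlap=float(ovl[best]),
                         argmax_mode=best + 1, n_modes_considered=n_consider)


def lsq_fit(t: Transition, modes: ModeSet, m: int,
            subset: AtomSubset | None = None,
            superpose: bool = True) -> FitResult:
    """Least-squares fit of the transition to the first ``m`` modes.

    With ``superpose`` (default), the unbound coordinates are first rigidly
    superposed onto the bound ones over the fitting subset, so the fit spends
    no coefficients absorbing rigid motion. The fitted deformation is applied
    to all paired atoms; residuals and RMSDs are evaluated on the subset.
    """
    if m < 1:
        raise ValueError("need at least one mode")
    local = _restrict(t, subset)
    D_full = t.unbound_coords
    E_sub = t.bound_coords[local]
    if superpose:
        R, tr = kabsch(D_full[local], E_sub)
        D_full = D_full @ R.T + tr
    rows_full = _mode_rows(t.atom_indices)
    M_all = np.asarray(modes.cartesian_modes[:, :m], float)[rows_full]
    if superpose:
        # rotate each mode's per-atom displacement into the superposed frame
        M_all = (M_all.reshape(-1, 3, m).transpose(2, 0, 1) @ R.T
                 ).transpose(1, 2, 0).reshape(-1, m)
    rows_local = (3 * local[:, None] + np.arange(3)).reshape(-1)
    M_sub = M_all[rows_local]
    T_sub = (E_sub - D_full[local]).reshape(-1)
    beta, _, rank, _ = np.linalg.lstsq(M_sub, T_sub, rcond=None)
    if rank < m:
        warnings.warn(f"rank-deficient mode basis (rank {rank} < {m}); "
                      "least-norm solution returned")
    fitted_full = D_full + (M_all @ beta).reshape(-1, 3)
    residual = T_sub - M_sub @ beta
    initial = rmsd(D_full[local], E_sub)
    fitted = rmsd(fitted_full[local], E_sub)
    reduction = 100.0 * (1.0 - fitted / initial) if initial > 0 else 0.0
    return FitResult(coefficients=beta, residual=residual,
                     sum_sq=float(residual @ residual),
                     fitted_coords=fitted_full, initial_rmsd=initial,
                     fitted_rmsd=fitted, percent_reduction=reduction,
                     mode_basis=M_sub, superposed=superpose)


@dataclass
class ReductionCurve:
    m_values: list
    percent_reduction: np.ndarray
    incremental_drops: np.ndarray      # RMSD drop when mode j is added, j=1..max(m)
    mode_of_greatest_influence: int    # 1-based


def reduction_curve(t: Transition, modes: ModeSet, m_values,
                    subset: AtomSubset | None = None,
                    superpose: bool = True) -> ReductionCurve:
    """Percent RMSD reduction as a function of basis size.

    Modes are added in frequency order; the mode of greatest influence is the
    one whose incremental addition produces the largest RMSD drop.
    """
    m_values = list(m_values)
    if m_values != sorted(m_values):
        raise ValueError("m_values must be ascending")
    m_max = max(m_values)
    rmsds = np.empty(m_max + 1)
    for m in range(1, m_max + 1):
        fit = lsq_fit(t, modes, m, subset=subset, superpose=superpose)
        rmsds[m] = fit.fitted_rmsd
        if m == 1:
            rmsds[0] = fit.initial_rmsd
    drops = rmsds[:-1] - rmsds[1:]
    reductions = np.array([100.0 * (1.0 - rmsds[m] / rmsds[0])
                           for m in m_values])
    return ReductionCurve(m_values=m_values, percent_reduction=reductions,
                          incremental_drops=drops,
                          mode_of_greatest_influence=int(np.argmax(drops)) + 1)


def ks_uniformity(argmax_modes, n_consider: int = 20) -> dict:
    """Two-sided KS statistic of mode numbers against a uniform distribution.

    The statistic is evaluated on the discrete support 1..n_consider (both the
    empirical and the reference CDF jump only at integers). Both the
    asymptotic 1% critical value 1.628/sqrt(n) and the exact finite-sample one
    are reported.
    """
    x = np.asarray(list(argmax_modes), dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("no mode numbers supplied")
    support = np.arange(1, n_consider + 1)
    ecdf = np.searchsorted(np.sort(x), support, side="right") / n
    ref = support / n_consider
    D = float(np.max(np.abs(ecdf - ref)))
    return {
        "D": D,
        "n": n,
        "D_crit_asymptotic_0.01": 1.628 / np.sqrt(n),
        "D_crit_exact_0.01": float(scipy.stats.kstwo.ppf(0.99, n)),
    }


@dataclass
class BenchmarkEntry:
    """One unbound→bound transition plus the bound binding partner.

    Structures may be given directly or as PDB paths (resolved lazily).
    """

    complex_id: str
    unbound: Structure | str
    bound: Structure | str
    bound_partner: Structure | str | None = None

    def load(self):
        def _s(x):
            return read_structure(x) if isinstance(x, str) else x
        return _s(self.unbound), _s(self.bound), (
            _s(self.bound_partner) if self.bound_partner is not None else None)


def benchmark_statistics(entries, n_consider: int = 20,
                         methods=("exact", "rtb"),
                         resolutions=("all", "backbone", "calpha"),
                         interface_cutoff: float = 6.0,
                         enm_params: EnmParams | None = None):
    """Per-pair and aggregate overlap statistics over a benchmark manifest.

    For every entry, method and atom resolution the maximum overlap and its
    mode number are computed across the whole fold and (when the bound
    partner is available) the binding interface, which is defined on the
    bound complex and mapped back to unbound atoms via the correspondence.

    Returns ``(per_pair, summary)`` DataFrames; the summary carries mean
    maximum overlap, the fraction of argmax modes ≤ 5, and the KS uniformity
    statistic of the argmax-mode distribution.
    """
    enm_params = enm_params or EnmParams()
    records = []
    for entry in entries:
        try:
            unbound, bound, partner = entry.load()
            corr = map_correspondence(unbound, bound)
            t = make_transition(unbound, bound, corr)
        except Exception as exc:
            logger.warning("skipping %s: %s", entry.complex_id, exc)
            continue
        regions: dict[str, AtomSubset | None] = {"fold": None}
        if partner is not None:
            iface_bound, _ = find_interface(bound, partner,
                                            cutoff=interface_cutoff)
            bound_to_unbound = {b: u for u, b in corr.pairs}
            iface_unbound = np.array(
                sorted(bound_to_unbound[i] for i in iface_bound.indices
                       if i in bound_to_unbound), dtype=int)
            if len(iface_unbound):
                regions["interface"] = AtomSubset("interface", iface_unbound)
        for method in methods:
            modes = compute_modes(unbound, enm_params, method=method)
            for res_kind in resolutions:
                sel = select_subset(unbound, res_kind)
                for region, reg_subset in regions.items():
                    if reg_subset is None:
                        idx = sel.indices
                    else:
                        idx = np.intersect1d(sel.indices, reg_subset.indices)
                    sub = AtomSubset("custom", idx)
                    try:
                        ores = max_overlap(modes, t, sub, n_consider=n_consider)
                    except ValueError as exc:
                        logger.warning("%s %s/%s/%s: %s", entry.complex_id,
                                       method, res_kind, region, exc)
                        continue
                    records.append({
                        "complex_id": entry.complex_id, "method": method,
                        "resolution": res_kind, "region": region,
                        "max_overlap": ores.max_overlap,
                        "argmax_mode": ores.argmax_mode,
                    })
    per_pair = pd.DataFrame.from_records(records)
    summaries = []
    if len(per_pair):
        for (method, res_kind, region), grp in per_pair.groupby(
                ["method", "resolution", "region"]):
            ks = ks_uniformity(grp["argmax_mode"], n_consider=n_consider)
            summaries.append({
                "method": method, "resolution": res_kind, "region": region,
                "mean_max_overlap": grp["max_overlap"].mean(),
                "frac_argmax_le_5": (grp["argmax_mode"] <= 5).mean(),
                "n_pairs": len(grp),
                "ks_D": ks["D"],
                "ks_D_crit_asymptotic_0.01": ks["D_crit_asymptotic_0.01"],
                "ks_D_crit_exact_0.01": ks["D_crit_exact_0.01"],
            })
    summary = pd.DataFrame.from_records(summaries)
    return per_pair, summary


def read_manifest(path) -> list[BenchmarkEntry]:
    """Read a TSV/CSV manifest with columns complex_id, unbound_pdb,
    bound_pdb and optionally bound_partner_pdb."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    entries = []
    for _, row in df.iterrows():
        entries.append(BenchmarkEntry(
            complex_id=str(row["complex_id"]),
            unbound=row["unbound_pdb"], bound=row["bound_pdb"],
            bound_partner=row.get("bound_partner_pdb", None)))
    return entries
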