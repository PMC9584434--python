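"""Synthetic six-gene core-oscillator benchmark.

A six-node Hill ODE system (genes A-F, unit decay, shared Hill exponent
n = 5) with the regulatory topology

    A : F          (activation)
    B : C          (activation)
    C : (A + E)(~D)
    D : (~A)(~E)
    E : (~B)(F)
    F : ~B

is integrated at three widely separated parameterizations to produce three
benchmark datasets with distinct dynamical behavior.  Each regulated pair
(X, Y) carries a basal rate Gamma_{X,Y}, a regulation amplitude
Omega_{X,Y} and a threshold theta_{X,Y}; production terms are
``Gamma + Omega * H(X)`` with ``H`` an activating or repressing Hill
function, summed within parenthesized groups and multiplied across groups.

A spurious sinusoid "gene" G can be appended as a true-negative control,
and a reduced five-gene system (node D deleted) probes which
parameterizations need D to sustain oscillation.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .timeseries import TimeSeriesSet

HILL_EXPONENT = 5.0

GENES = ("A", "B", "C", "D", "E", "F")

#: The ten regulated (source, target) pairs, with parameter values
#: (Gamma, Omega, theta) for each of the three benchmark parameterizations.
GROUND_TRUTH_PARAMS: dict[tuple[str, str], tuple[tuple[float, float, float], ...]] = {
    ("B", "F"): ((0.1071294686, 1.1980739800, 0.0055430383),
                 (0.1247062357, 2.6962820818, 0.3637389501),
                 (0.1054951481, 2.0937997708, 0.5673228474)),
    ("F", "E"): ((0.0175034071, 0.8244263241, 1.3029576011),
                 (0.5011731410, 0.1209518139, 1.5201526697),
                 (0.2455250910, 1.5683516101, 0.8518129907)),
    ("C", "B"): ((0.0011155796, 1.9491367094, 2.9810640658),
                 (0.1958127811, 1.5533875523, 3.5689954379),
                 (0.0966678191, 2.3227225179, 3.1482725035)),
    ("E", "D"): ((0.2201158863, 3.6625872030, 0.5390177462),
                 (0.2141223259, 2.9847903373, 1.0533043028),
                 (0.0529032838, 0.5576409019, 0.3727988706)),
    ("E", "C"): ((1.6499211746, 0.3900059619, 0.0088027178),
                 (0.4358121924, 0.5490600005, 1.4982296668),
                 (0.0676798151, 1.7873719546, 1.4187706085)),
    ("A", "C"): ((0.1007846993, 0.2578132626, 0.2419230934),
                 (0.4132072556, 2.2969011759, 0.6819105357),
                 (0.0928646536, 1.2197732691, 1.7352137828)),
    ("B", "E"): ((0.0096494654, 0.7130182868, 1.5106988697),
                 (0.2810071904, 2.2758756351, 0.6517967757),
                 (0.6185173324, 3.7129348824, 0.7417231063)),
    ("A", "D"): ((0.0542085170, 0.8946601377, 0.6862437739),
                 (0.1210124702, 2.0147888846, 1.1760092769),
                 (0.2731054750, 0.5576412929, 0.4867821250)),
    ("D", "C"): ((0.0624991995, 1.3297386450, 1.0817547392),
                 (1.1124366444, 3.2764296326, 2.1191576389),
                 (0.2593204887, 4.0461307096, 0.1931413047)),
    ("F", "A"): ((0.1885194202, 1.4488910403, 0.7285164419),
                 (0.0567438444, 2.1341889294, 0.3815742876),
                 (0.0398781756, 6.1842079625, 1.4900313815)),
}

#: Text form of the ground-truth network (see :mod:`oscnet.netspec`).
GROUND_TRUTH_NETWORK = """\
A : F
B : C
C : (A + E)(~D)
D : (~A)(~E)
E : (~B)(F)
F : ~B
"""

#: Default simulation grid: long enough to discard the first half as a
#: transient and keep at least three full periods of the slowest
#: parameterization (period ~10.75) at >= 20 samples per period.
DEFAULT_T_END = 80.0
DEFAULT_DT = 0.05
DEFAULT_TRANSIENT_FRACTION = 0.5

#: Default angular frequency of the spurious sinusoid G.
DEFAULT_OMEGA_G = 4.5 * np.pi


def default_t_grid(t_end: float = DEFAULT_T_END, dt: float = DEFAULT_DT) -> np.ndarray:
    return np.arange(0.0, t_end + dt / 2, dt)


def _act(x: np.ndarray, theta: float, n: float) -> np.ndarray:
    xn = x ** n
    return xn / (xn + theta ** n)


def _rep(x: np.ndarray, theta: float, n: float) -> np.ndarray:
    tn = theta ** n
    return tn / (x ** n + tn)


def _params(column: int) -> dict[tuple[str, str], tuple[float, float, float]]:
    if column not in (1, 2, 3):
        raise ValueError(f"param_column must be 1, 2 or 3, got {column}")
    return {pair: vals[column - 1] for pair, vals in GROUND_TRUTH_PARAMS.items()}


def _term(p, pair, x, kind, n=HILL_EXPONENT):
    g, om, th = p[pair]
    h = _act(x, th, n) if kind == "a" else _rep(x, th, n)
    return g + om * h


def simulate_ground_truth(param_column: int,
                          t_grid: np.ndarray | None = None,
                          x0: np.ndarray | None = None,
                          include_spurious: bool = False,
                          omega_g: float = DEFAULT_OMEGA_G,
                          rtol: float = 1e-9,
                          atol: float = 1e-11) -> TimeSeriesSet:
    """Integrate the six-gene system and sample it on ``t_grid``.

    ``param_column`` selects one of the three stored parameterizations.
    With ``include_spurious``, the sinusoid G is appended as a seventh
    trace.  Initial condition defaults to 1.0 for every gene.
    """
    p = _params(param_column)
    t = default_t_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    y0 = np.ones(6) if x0 is None else np.asarray(x0, dtype=float)

    def rhs(_t, y):
        A, B, C, D, E, F = y
        return (
            -A + _term(p, ("F", "A"), F, "a"),
            -B + _term(p, ("C", "B"), C, "a"),
            -C + (_term(p, ("A", "C"), A, "a") + _term(p, ("E", "C"), E, "a"))
                 * _term(p, ("D", "C"), D, "r"),
            -D + _term(p, ("A", "D"), A, "r") * _term(p, ("E", "D"), E, "r"),
            -E + _term(p, ("B", "E"), B, "r") * _term(p, ("F", "E"), F, "a"),
            -F + _term(p, ("B", "F"), B, "r"),
        )

    sol = solve_ivp(rhs, (t[0], t[-1]), y0, t_eval=t, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed for column {param_column}: {sol.message}")
    names = list(GENES)
    values = sol.y
    if include_spurious:
        names = names + ["G"]
        values = np.vstack([values, spurious_wave(t, omega_g)])
    return TimeSeriesSet(names, t, values, replicate_id=f"column{param_column}")


def simulate_reduced(param_column: int,
                     t_grid: np.ndarray | None = None,
                     x0: np.ndarray | None = None,
                     rtol: float = 1e-9,
                     atol: float = 1e-11) -> TimeSeriesSet:
    """Integrate the five-gene reduction in which node D is removed.

    Node C then receives the bare sum of its activating inputs from A and
    E; everything else is unchanged.
    """
    p = _params(param_column)
    t = default_t_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    y0 = np.ones(5) if x0 is None else np.asarray(x0, dtype=float)

    def rhs(_t, y):
        A, B, C, E, F = y
        return (
            -A + _term(p, ("F", "A"), F, "a"),
            -B + _term(p, ("C", "B"), C, "a"),
            -C + _term(p, ("A", "C"), A, "a") + _term(p, ("E", "C"), E, "a"),
            -E + _term(p, ("B", "E"), B, "r") * _term(p, ("F", "E"), F, "a"),
            -F + _term(p, ("B", "F"), B, "r"),
        )

    sol = solve_ivp(rhs, (t[0], t[-1]), y0, t_eval=t, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed for reduced column {param_column}: {sol.message}")
    return TimeSeriesSet(["A", "B", "C", "E", "F"], t, sol.y,
                         replicate_id=f"reduced_column{param_column}")


def spurious_wave(t_grid: np.ndarray, omega: float = DEFAULT_OMEGA_G,
                  amplitude: float = 2.0) -> np.ndarray:
    """The true-negative trace ``amplitude * (sin(omega t) + 1)``.

    Range ``[0, 2*amplitude]``, mean ``amplitude`` over whole periods.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    t = np.asarray(t_grid, dtype=float)
    return amplitude * (np.sin(omega * t) + 1.0)


def fold_change_check(ts: TimeSeriesSet,
                      transient_fraction: float = DEFAULT_TRANSIENT_FRACTION) -> float:
    """Minimum over genes of peak/trough ratio on the post-transient window.

    The benchmark simulations are required to show at least a four-fold
    change for every gene once the transient is discarded.
    """
    t0 = ts.times[0] + transient_fraction * (ts.times[-1] - ts.times[0])
    post = ts.values[:, ts.times >= t0]
    troughs = post.min(axis=1)
    if np.any(troughs <= 0):
        bad = ts.gene_names[int(np.argmin(troughs))]
        raise ValueError(f"nonpositive post-transient trough for gene {bad}")
    return float(np.min(post.max(axis=1) / troughs))


def make_benchmark_dataset(param_column: int,
                           include_spurious: bool = True,
                           t_grid: np.ndarray | None = None) -> TimeSeriesSet:
    """One of the three benchmark datasets (A-F plus the spurious G)."""
    return simulate_ground_truth(param_column, t_grid=t_grid,
                                 include_spurious=include_spurious)


def write_parameter_table(path) -> None:
    """Dump the stored three-column parameter table as a TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("parameter\tcolumn1\tcolumn2\tcolumn3\n")
        for (src, tgt), cols in GROUND_TRUTH_PARAMS.items():
            for name, idx in (("Gamma", 0), ("Omega", 1), ("theta", 2)):
                vals = "\t".join(f"{c[idx]:.10f}" for c in cols)
                fh.write(f"{name}_{src},{tgt}\t{vals}\n")
        fh.write(f"n\t5\t5\t5\n")
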