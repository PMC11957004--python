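"""Multi-Gaussian fitting of blockage-amplitude distributions.

The species populations of a nanopore recording (short cfDNA-like target,
1 kbp internal marker, HMW genomic DNA) separate on the blockage-amplitude
axis. A 1-D Gaussian mixture is fitted to the *raw* event amplitudes by
expectation-maximization (histograms are for reporting only); the expected
event count of each species is the responsibility-weighted "soft count" —
the area under its fitted Gaussian — which degrades gracefully when
components overlap. Mixture order is either fixed (three components for the
standard mock) or selected by BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.mixture import GaussianMixture

from .detect import EventTable
from .errors import FitFailureError, InvalidParameterError
from .quantify import FrequencySet

__all__ = [
    "AmplitudeHistogram",
    "MixtureComponent",
    "MixtureFit",
    "amplitude_histogram",
    "fit_mixture",
    "select_components",
    "label_components",
    "species_frequencies",
]

SPECIES_ORDER = ("target", "marker", "gdna")
SD_FLOOR_PA = 1e-3


@dataclass(frozen=True)
class AmplitudeHistogram:
    """Counts distribution of blockage amplitudes (reporting only)."""

    bin_edges: np.ndarray  # pA, strictly increasing
    counts: np.ndarray  # non-negative ints, one fewer than edges


def amplitude_histogram(amplitudes: np.ndarray, bins="fd") -> AmplitudeHistogram:
    """Histogram of amplitudes with Freedman-Diaconis binning by default."""
    counts, edges = np.histogram(np.asarray(amplitudes, dtype=float), bins=bins)
    return AmplitudeHistogram(bin_edges=edges, counts=counts)


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean_pA: float
    sd_pA: float
    soft_count: float
    species_label: str = "unassigned"


@dataclass(frozen=True)
class MixtureFit:
    """A fitted (and optionally labelled) Gaussian mixture over amplitudes."""

    components: tuple[MixtureComponent, ...]
    log_likelihood: float
    bic: float
    converged: bool
    n_events: int
    responsibilities: np.ndarray = field(repr=False, default=None)  # (n, K), component order
    labelled: bool = False

    @property
    def n_components(self) -> int:
        return len(self.components)

    def component(self, label: str) -> MixtureComponent | None:
        for c in self.components:
            if c.species_label == label:
                return c
        return None

    def soft_count(self, label: str) -> float:
        c = self.component(label)
        return 0.0 if c is None else c.soft_count


def fit_mixture(
    amplitudes: np.ndarray,
    n_components: int,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    max_restarts: int = 5,
) -> MixtureFit:
    """EM fit of a 1-D Gaussian mixture to raw blockage amplitudes.

    Runs ``n_init`` k-means++-seeded restarts and keeps the best likelihood.
    A component whose sd collapses below 1e-3 pA is treated as degenerate and
    the whole fit is restarted with a perturbed seed; if every restart
    degenerates a :class:`FitFailureError` is raised. Deterministic given
    (data, n_components, seed). Components are reported sorted by mean.
    """
    x = np.asarray(amplitudes, dtype=float).reshape(-1, 1)
    n = len(x)
    if n < 10 * n_components:
        raise InvalidParameterError(
            f"need at least {10 * n_components} events for K={n_components} (got {n})"
        )
    for attempt in range(max_restarts):
        gmm = GaussianMixture(
            n_components=n_components,
            covariance_type="full",
            tol=tol,
            max_iter=max_iter,
            n_init=n_init,
            init_params="k-means++",
            reg_covar=1e-12,
            random_state=seed + 1_000_003 * attempt,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gmm.fit(x)
        sds = np.sqrt(gmm.covariances_.reshape(-1))
        if np.all(sds >= SD_FLOOR_PA):
            break
    else:
        raise FitFailureError(
            f"all {max_restarts} restarts produced a degenerate component (sd < {SD_FLOOR_PA} pA)"
        )
    order = np.argsort(gmm.means_.reshape(-1))
    resp = gmm.predict_proba(x)[:, order]
    soft = resp.sum(axis=0)
    comps = tuple(
        MixtureComponent(
            weight=float(gmm.weights_[j]),
            mean_pA=float(gmm.means_[j, 0]),
            sd_pA=float(sds[j]),
            soft_count=float(soft[i]),
        )
        for i, j in enumerate(order)
    )
    return MixtureFit(
        components=comps,
        log_likelihood=float(gmm.score(x) * n),
        bic=float(gmm.bic(x)),
        converged=bool(gmm.converged_),
        n_events=n,
        responsibilities=resp,
    )


def select_components(
    amplitudes: np.ndarray,
    k_max: int = 4,
    seed: int = 0,
    **fit_kwargs,
) -> MixtureFit:
    """Fit K = 1..k_max mixtures and return the BIC-optimal one.

    Ties break toward smaller K. Individual K failures are tolerated as long
    as at least one order fits.
    """
    if k_max < 1:
        raise InvalidParameterError("k_max must be >= 1")
    best: MixtureFit | None = None
    last_err: Exception | None = None
    for k in range(1, k_max + 1):
        try:
            fit = fit_mixture(amplitudes, k, seed=seed, **fit_kwargs)
        except (FitFailureError, InvalidParameterError) as err:
            last_err = err
            continue
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise FitFailureError(f"no mixture order in 1..{k_max} could be fitted: {last_err}")
    return best


def label_components(
    fit: MixtureFit, marker_amplitude_hint_pA: float | None = None
) -> MixtureFit:
    """Assign species labels (target / marker / gdna) to mixture components.

    With three components the amplitude ordering is total: smallest mean is
    the short target, middle the 1 kbp marker, largest the HMW gDNA. With
    fewer components a marker amplitude hint is required: the component
    nearest the hint is the marker, anything below it is target, anything
    above gdna; absent species simply contribute zero soft count. With more
    than three components the surplus smallest-weight components are left
    unassigned (with a warning) and the remaining three labelled by order.
    """
    if not fit.converged:
        raise FitFailureError("cannot label an unconverged fit")
    comps = list(fit.components)  # already sorted by mean
    k = len(comps)
    labels = ["unassigned"] * k
    if k == 3:
        labels = list(SPECIES_ORDER)
    elif k > 3:
        warnings.warn(
            f"{k - 3} surplus mixture component(s) left unassigned", stacklevel=2
        )
        weights = np.array([c.weight for c in comps])
        keep = np.sort(np.argsort(weights)[-3:])
        for lab, idx in zip(SPECIES_ORDER, keep):
            labels[idx] = lab
    else:  # k < 3: need the marker hint to anchor the scale
        if marker_amplitude_hint_pA is None:
            raise InvalidParameterError(
                f"K={k} < 3 components: a marker_amplitude_hint_pA is required to "
                "identify the internal marker"
            )
        means = np.array([c.mean_pA for c in comps])
        marker_idx = int(np.argmin(np.abs(means - marker_amplitude_hint_pA)))
        labels[marker_idx] = "marker"
        for i in range(k):
            if i == marker_idx:
                continue
            labels[i] = "target" if means[i] < means[marker_idx] else "gdna"
    new_comps = tuple(replace(c, species_label=lab) for c, lab in zip(comps, labels))
    return replace(fit, components=new_comps, labelled=True)


def species_frequencies(fit: MixtureFit, table: EventTable) -> FrequencySet:
    """Per-species event frequencies f_s = soft_count(s) / effective duration."""
    if not fit.labelled:
        raise InvalidParameterError("mixture fit must be labelled before computing frequencies")
    if not table.effective_duration_s > 0:
        raise InvalidParameterError("effective duration must be positive")
    dur = table.effective_duration_s
    return FrequencySet(
        f_target=fit.soft_count("target") / dur,
        f_marker=fit.soft_count("marker") / dur,
        f_gdna=fit.soft_count("gdna") / dur,
    )
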