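"""sklearn-style estimator facade for the fit/transform-shaped stages.

These compose with sklearn pipelines and model selection; the module-level
functions in matrix/selection/network/discovery are thin functional
equivalents.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator

from .background import MarkovBackground, train_markov_background
from .discovery import MotifParams, discover_motifs_zoops
from .matrix import QuantileNormalizer
from .network import CoexpressionClusterer
from .selection import DiscriminativeArraySelector

__all__ = [
    "QuantileNormalizer",
    "DiscriminativeArraySelector",
    "CoexpressionClusterer",
    "ZoopsMotifFinder",
]


class ZoopsMotifFinder(BaseEstimator):
    """Discover up to ``n_motifs`` motifs in a set of promoter sequences by
    sequential ZOOPS EM against an order-k Markov background.

    Parameters mirror :class:`coexmotif.discovery.MotifParams`; the fit
    input is a PromoterSet, a mapping name -> sequence, or a list of
    sequences.

    Attributes
    ----------
    motifs_ : list of Motif, ordered by log-likelihood-ratio objective.
    background_ : MarkovBackground trained on (or supplied for) the input.
    """

    def __init__(self, n_motifs: int = 10, w_min: int = 6, w_max: int = 12,
                 background_order: int = 3, max_iter: int = 200,
                 tol: float = 1e-6, max_seeds: int = 1000, n_starts: int = 3,
                 both_strands: bool = True, seed: int = 0):
        self.n_motifs = n_motifs
        self.w_min = w_min
        self.w_max = w_max
        self.background_order = background_order
        self.max_iter = max_iter
        self.tol = tol
        self.max_seeds = max_seeds
        self.n_starts = n_starts
        self.both_strands = both_strands
        self.seed = seed

    def _params(self) -> MotifParams:
        return MotifParams(n_motifs=self.n_motifs, w_min=self.w_min,
                           w_max=self.w_max, background_order=self.background_order,
                           max_iter=self.max_iter, tol=self.tol,
                           max_seeds=self.max_seeds, n_starts=self.n_starts,
                           both_strands=self.both_strands, seed=self.seed)

    def fit(self, X, y=None, background: MarkovBackground | None = None):
        params = self._params()
        if background is None:
            background = train_markov_background(
                X, k=self.background_order, both_strands=self.both_strands)
        self.background_ = background
        self.motifs_ = discover_motifs_zoops(X, params, background)
        return self
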