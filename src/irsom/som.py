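"""Kohonen self-organising map engine for spectral structure fitting.

The workflow has three steps. (i) *Training*: a square grid of nodes, each
holding a candidate spectrum, self-organises on the reference spectra — at
every step a randomly chosen reference spectrum pulls its best-matching node
and that node's grid neighbourhood towards itself, with learning rate and
neighbourhood radius decaying exponentially. (ii) *Structure assignment*:
nodes where a reference member lands take that member's structure fractions;
every other node gets an inverse-distance-weighted average of all members'
fractions, the distance being Euclidean in spectral space. (iii) *Prediction*:
an unknown spectrum is matched to its k best matching units (BMUs) and its
structure is the inverse-distance-weighted average of their fractions; the
same weights reconstruct a predicted spectrum whose NRMSD against the input
measures fit quality.

The model/results split follows common statistical-modelling practice:
:class:`KohonenSOM` is built from a :class:`~irsom.spectra.ReferenceSet` and a
:class:`SOMConfig`; ``fit()`` returns a :class:`TrainedMap` carrying node
spectra, node structures, reference placements and diagnostics, with
``predict()``, ``summary()`` and ``save()``/``load()``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .spectra import ReferenceSet, Spectrum, StructureFractions

__all__ = [
    "SOMConfig",
    "KohonenSOM",
    "TrainedMap",
    "PredictionResult",
    "train",
    "assign_structures",
    "find_bmus",
    "predict",
    "nrmsd",
    "save_map",
    "load_map",
    "default_map_dim",
    "GridMismatchError",
]


class GridMismatchError(ValueError):
    """Test spectrum grid does not match the trained map's grid."""


def default_map_dim(n_members: int) -> int:
    """Map side length for a reference set of given size.

    Large (~50-member) sets use 40x40 and mid-sized (~30) sets 20x20 — the
    choices validated for film and solid-state reference sets; smaller sets
    scale as ceil(4*sqrt(N)), capped at 40.
    """
    if n_members >= 45:
        return 40
    if n_members >= 25:
        return 20
    return min(40, max(2, math.ceil(4 * math.sqrt(n_members))))


@dataclass(frozen=True)
class SOMConfig:
    """Training/prediction hyper-parameters.

    map_dim defaults to :func:`default_map_dim` of the reference-set size at
    fit time. Learning rate alpha and neighbourhood radius sigma both decay
    exponentially from their initial to final values over n_steps; sigma0
    defaults to map_dim/2 at fit time.
    """

    map_dim: int | None = None
    n_steps: int = 50_000
    alpha0: float = 0.25
    alpha_end: float = 0.01
    sigma0: float | None = None
    sigma_end: float = 0.5
    seed: int = 0
    k_bmu: int = 5                  # 5 or 3 in routine use
    weighting_power: float = 3.0    # p in 1/d^p structure weights

    def __post_init__(self) -> None:
        if self.map_dim is not None and self.map_dim < 2:
            raise ValueError("map_dim must be >= 2")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not (0 < self.alpha_end <= self.alpha0 <= 1):
            raise ValueError("need 0 < alpha_end <= alpha0 <= 1")
        if self.sigma_end <= 0:
            raise ValueError("sigma_end must be > 0")
        if self.k_bmu < 1:
            raise ValueError("k_bmu must be >= 1")

    def resolve(self, n_members: int) -> "SOMConfig":
        """Fill map_dim and sigma0 defaults for a given reference-set size."""
        dim = self.map_dim if self.map_dim is not None else default_map_dim(n_members)
        sig0 = self.sigma0 if self.sigma0 is not None else dim / 2.0
        return SOMConfig(dim, self.n_steps, self.alpha0, self.alpha_end,
                         sig0, self.sigma_end, self.seed, self.k_bmu,
                         self.weighting_power)


def nrmsd(observed, predicted) -> float:
    """Normalised root-mean-square deviation sqrt(sum((o-p)^2) / sum(o^2))."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed and predicted must have equal length")
    denom = float(o @ o)
    if denom == 0.0:
        raise ValueError("observed vector has zero norm; NRMSD undefined")
    return math.sqrt(float((o - p) @ (o - p)) / denom)


@dataclass(frozen=True)
class PredictionResult:
    """Structure estimate for one test spectrum.

    bmus is the ordered (ascending spectral distance) list of
    ((row, col), distance) pairs actually used in the weighted average;
    reconstructed is the same-weighted combination of BMU node spectra and
    nrmsd its deviation from the input.
    """

    label: str
    fractions: StructureFractions
    bmus: tuple
    reconstructed: np.ndarray
    nrmsd: float


@dataclass
class TrainedMap:
    """Fitted self-organising map (results object).

    node_spectra has shape (map_dim**2, n_points) in row-major node order;
    node index i sits at grid position (i // map_dim, i % map_dim).
    """

    map_dim: int
    wavenumber_grid: np.ndarray
    node_spectra: np.ndarray
    node_structures: np.ndarray            # (n_nodes, 3) helix/sheet/other
    reference_placements: dict[str, tuple[int, int]]
    config: SOMConfig
    quantization_errors: list[float] = field(default_factory=list)

    # -- geometry -----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.map_dim * self.map_dim

    def node_coord(self, index: int) -> tuple[int, int]:
        return index // self.map_dim, index % self.map_dim

    def node_index(self, coord: tuple[int, int]) -> int:
        return coord[0] * self.map_dim + coord[1]

    def grid_positions(self) -> np.ndarray:
        """(n_nodes, 2) array of (row, col) in row-major order."""
        r, c = np.divmod(np.arange(self.n_nodes), self.map_dim)
        return np.column_stack([r, c])

    # -- prediction ---------------------------------------------------------
    def _check_grid(self, s: Spectrum) -> None:
        if s.wavenumbers.shape != self.wavenumber_grid.shape or not np.allclose(
            s.wavenumbers, self.wavenumber_grid
        ):
            raise GridMismatchError(
                "test spectrum grid differs from the map's training grid"
            )

    def find_bmus(self, s: Spectrum, k: int | None = None) -> list:
        """The k nodes nearest to s in spectral space, ascending distance.

        Ties are broken towards the lower row-major node index (stable sort).
        """
        self._check_grid(s)
        k = self.config.k_bmu if k is None else k
        if k > self.n_nodes:
            raise ValueError(f"k={k} exceeds node count {self.n_nodes}")
        d = np.linalg.norm(self.node_spectra - s.absorbance, axis=1)
        order = np.argsort(d, kind="stable")[:k]
        return [(self.node_coord(int(i)), float(d[i])) for i in order]

    def predict(self, s: Spectrum, k: int | None = None) -> PredictionResult:
        """Estimate structure fractions of a (normalised) test spectrum.

        Inverse-distance weights over the k BMUs; if any BMU matches exactly
        (zero distance), the result is the plain mean over all zero-distance
        BMUs, which keeps the estimate a convex combination.
        """
        bmus = self.find_bmus(s, k)
        idx = np.array([self.node_index(c) for c, _ in bmus])
        d = np.array([dist for _, dist in bmus])
        if np.any(d == 0.0):
            sel = d == 0.0
            w = sel.astype(float)
        else:
            w = 1.0 / d
        w = w / w.sum()
        frac = w @ self.node_structures[idx]
        # renormalise only when fp drift is measurable, so an exact node match
        # returns that node's stored fractions bit-for-bit
        if np.any(frac < 0.0) or abs(frac.sum() - 1.0) > 1e-12:
            frac = np.clip(frac, 0.0, None)
            frac = frac / frac.sum()
        recon = w @ self.node_spectra[idx]
        return PredictionResult(
            label=s.label,
            fractions=StructureFractions.from_array(frac),
            bmus=tuple(bmus),
            reconstructed=recon,
            nrmsd=nrmsd(s.absorbance, recon),
        )

    def predict_many(self, spectra, k: int | None = None) -> list[PredictionResult]:
        return [self.predict(s, k) for s in spectra]

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Trained self-organising map",
            "---------------------------",
            f"map dimension        : {self.map_dim} x {self.map_dim} "
            f"({self.n_nodes} nodes)",
            f"spectral grid        : {self.wavenumber_grid.size} points, "
            f"{self.wavenumber_grid[0]:.1f}-{self.wavenumber_grid[-1]:.1f} cm^-1",
            f"reference members    : {len(self.reference_placements)}",
            f"training steps       : {cfg.n_steps}",
            f"alpha schedule       : {cfg.alpha0} -> {cfg.alpha_end}",
            f"sigma schedule       : {cfg.sigma0} -> {cfg.sigma_end}",
            f"seed                 : {cfg.seed}",
        ]
        if self.quantization_errors:
            lines.append(
                f"final quantization   : {self.quantization_errors[-1]:.6g}"
            )
        occupied = len(set(self.reference_placements.values()))
        lines.append(f"occupied nodes       : {occupied}")
        return "\n".join(lines)

    def placements_table(self):
        """(label, row, col) rows for plotting the map layout externally."""
        return [(lab, r, c) for lab, (r, c) in self.reference_placements.items()]

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        save_map(self, path)

    @classmethod
    def load(cls, path) -> "TrainedMap":
        return load_map(path)


class KohonenSOM:
    """Self-organising map model over a spectral reference set.

    Parameters
    ----------
    refset : ReferenceSet
        Training spectra with known structure fractions on a common grid.
    config : SOMConfig, optional
        Hyper-parameters; keyword overrides are applied on top.

    Examples
    --------
    >>> model = KohonenSOM(refset, n_steps=20_000, seed=7)   # doctest: +SKIP
    >>> trained = model.fit()                                # doctest: +SKIP
    >>> trained.predict(spectrum).fractions                  # doctest: +SKIP
    """

    def __init__(self, refset: ReferenceSet, config: SOMConfig | None = None,
                 **overrides):
        if config is None:
            config = SOMConfig(**overrides)
        elif overrides:
            config = SOMConfig(**{**asdict(config), **overrides})
        self.refset = refset
        self.config = config.resolve(len(refset))
        data = refset.spectra_matrix()
        if not np.all(np.isfinite(data)):
            raise ValueError("reference set contains non-finite absorbances")

    def fit(self, checkpoint_every: int | None = None) -> TrainedMap:
        """Run the online Kohonen updates and assign node structures.

        checkpoint_every logs the mean member-to-BMU distance (quantization
        error) every that many steps, for convergence diagnostics.
        """
        cfg = self.config
        data = self.refset.spectra_matrix()           # (N, n_pts)
        n, n_pts = data.shape
        dim = cfg.map_dim
        rng = np.random.default_rng(cfg.seed)

        lo, hi = data.min(axis=0), data.max(axis=0)
        nodes = rng.uniform(lo, hi, size=(dim * dim, n_pts))

        pos = np.column_stack(np.divmod(np.arange(dim * dim), dim)).astype(float)
        alpha_ratio = cfg.alpha_end / cfg.alpha0
        sigma_ratio = cfg.sigma_end / cfg.sigma0

        qerrs: list[float] = []
        picks = rng.integers(0, n, size=cfg.n_steps)
        for t in range(cfg.n_steps):
            frac = t / cfg.n_steps
            alpha = cfg.alpha0 * alpha_ratio ** frac
            sigma = cfg.sigma0 * sigma_ratio ** frac
            x = data[picks[t]]
            diff = x - nodes                                    # (n_nodes, n_pts)
            d2 = np.einsum("ij,ij->i", diff, diff)
            winner = int(np.argmin(d2))
            g2 = np.sum((pos - pos[winner]) ** 2, axis=1)
            h = np.exp(-g2 / (2.0 * sigma * sigma))
            nodes += (alpha * h)[:, None] * diff
            if checkpoint_every and (t + 1) % checkpoint_every == 0:
                qerrs.append(self._quantization_error(nodes, data))
        qerrs.append(self._quantization_error(nodes, data))

        placements = self._place_members(nodes, data)
        tm = TrainedMap(
            map_dim=dim,
            wavenumber_grid=self.refset.grid.copy(),
            node_spectra=nodes,
            node_structures=np.zeros((dim * dim, 3)),
            reference_placements=placements,
            config=cfg,
            quantization_errors=qerrs,
        )
        assign_structures(tm, self.refset, p=cfg.weighting_power)
        return tm

    @staticmethod
    def _quantization_error(nodes: np.ndarray, data: np.ndarray) -> float:
        d = np.linalg.norm(data[:, None, :] - nodes[None, :, :], axis=2)
        return float(d.min(axis=1).mean())

    def _place_members(self, nodes: np.ndarray, data: np.ndarray) -> dict:
        placements = {}
        dim = self.config.map_dim
        for j, (label, _, _) in enumerate(self.refset.members):
            d = np.linalg.norm(nodes - data[j], axis=1)
            i = int(np.argmin(d))  # argmin returns the lowest index on ties
            placements[label] = (i // dim, i % dim)
        return placements


def assign_structures(tmap: TrainedMap, refset: ReferenceSet,
                      p: float = 1.0) -> TrainedMap:
    """Assign structure fractions to every node (in place; also returned).

    Placement nodes copy their member's fractions exactly (when several
    members share a node, the spectrally nearest wins). Every other node
    takes the 1/d^p inverse-distance-weighted average of all members'
    fractions, d being the Euclidean distance between node spectrum and
    member spectrum; a zero distance short-circuits to that member's exact
    fractions.
    """
    data = refset.spectra_matrix()
    fracs = refset.fractions_matrix()
    labels = refset.labels
    nodes = tmap.node_spectra
    out = np.empty((tmap.n_nodes, 3))

    # distances: (n_nodes, N)
    d = np.linalg.norm(nodes[:, None, :] - data[None, :, :], axis=2)

    placed: dict[int, int] = {}
    for j, label in enumerate(labels):
        ni = tmap.node_index(tmap.reference_placements[label])
        if ni not in placed or d[ni, j] < d[ni, placed[ni]]:
            placed[ni] = j

    for i in range(tmap.n_nodes):
        if i in placed:
            out[i] = fracs[placed[i]]
            continue
        di = d[i]
        zero = di == 0.0
        if np.any(zero):
            out[i] = fracs[np.argmax(zero)]
            continue
        w = 1.0 / di ** p
        f = w @ fracs / w.sum()
        out[i] = np.clip(f, 0.0, None)
        out[i] /= out[i].sum()

    tmap.node_structures = out
    return tmap


# -- functional front-end (thin wrappers over the model/results objects) ----

def train(refset: ReferenceSet, cfg: SOMConfig | None = None, **overrides
          ) -> TrainedMap:
    """Train a map on a reference set; see :class:`KohonenSOM`."""
    return KohonenSOM(refset, cfg, **overrides).fit()


def find_bmus(tmap: TrainedMap, s: Spectrum, k: int | None = None):
    return tmap.find_bmus(s, k)


def predict(tmap: TrainedMap, s: Spectrum, k: int | None = None
            ) -> PredictionResult:
    return tmap.predict(s, k)


# -- persistence (JSON text; maps are small: n_nodes x grid floats) ----------

def save_map(tmap: TrainedMap, path) -> None:
    payload = {
        "format": "irsom-trained-map",
        "version": 1,
        "map_dim": tmap.map_dim,
        "wavenumber_grid": tmap.wavenumber_grid.tolist(),
        "node_spectra": tmap.node_spectra.tolist(),
        "node_structures": tmap.node_structures.tolist(),
        "reference_placements": {k: list(v)
                                 for k, v in tmap.reference_placements.items()},
        "config": asdict(tmap.config),
        "quantization_errors": tmap.quantization_errors,
    }
    Path(path).write_text(json.dumps(payload))


def load_map(path) -> TrainedMap:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "irsom-trained-map":
        raise ValueError(f"{path}: not a trained-map file")
    return TrainedMap(
        map_dim=payload["map_dim"],
        wavenumber_grid=np.array(payload["wavenumber_grid"]),
        node_spectra=np.array(payload["node_spectra"]),
        node_structures=np.array(payload["node_structures"]),
        reference_placements={k: tuple(v)
                              for k, v in payload["reference_placements"].items()},
        config=SOMConfig(**payload["config"]),
        quantization_errors=list(payload["quantization_errors"]),
    )
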