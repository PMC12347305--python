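"""Fragment library, six-residue torsion prediction and initial assembly.

Stage 1 of the pipeline predicts backbone torsions (phi, psi, omega) for
consecutive, non-overlapping six-residue windows of the target sequence;
stage 2 concatenates the predictions into a preliminary torsion-angle
model, filling any remainder residues (L mod 6) and all side-chain chi
angles with random values for the refinement stage to optimize.

Two interchangeable predictor backends are provided: a small convolutional
network trained on a fragment library, and a deterministic lookup that
retrieves the best-matching library fragment — the latter makes the full
pipeline testable without any training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .geometry import TorsionState, wrap_angle, wrap_angles
from .io_formats import AMINO_ACIDS, AminoAcidSequence, load_topology
from .nn import TinyConvNet

__all__ = [
    "Fragment",
    "FragmentLibrary",
    "PredictorConfig",
    "split_windows",
    "generate_synthetic_library",
    "fit_fragment_predictor",
    "predict_torsions",
    "assemble_initial_state",
    "LookupPredictor",
    "CNNPredictor",
]

WINDOW = 6
SS_LABELS = ("alpha", "beta", "loop")

# idealized backbone dihedral centers (deg) for the synthetic generator
ALPHA_CENTER = (-57.0, -47.0)
BETA_CENTER = (-139.0, 135.0)
LOOP_PHI_RANGE = (-160.0, -45.0)  # Ramachandran-permissive phi band
OMEGA_CENTER = 180.0


@dataclass(frozen=True)
class Fragment:
    """Six residues with their 18 backbone torsions and a secondary-structure label."""

    sequence: str
    phi: tuple[float, ...]
    psi: tuple[float, ...]
    omega: tuple[float, ...]
    ss_label: str

    def __post_init__(self):
        if len(self.sequence) != WINDOW:
            raise DomainError(f"fragment sequence must have {WINDOW} residues")
        if self.ss_label not in SS_LABELS:
            raise DomainError(f"unknown secondary-structure label {self.ss_label!r}")
        for name in ("phi", "psi", "omega"):
            vals = getattr(self, name)
            if len(vals) != WINDOW:
                raise DomainError(f"fragment needs {WINDOW} {name} angles")
            object.__setattr__(self, name, tuple(float(wrap_angle(v)) for v in vals))

    def angles(self) -> np.ndarray:
        """The 18 angles in predictor output order: 6 phi, 6 psi, 6 omega."""
        return np.array(self.phi + self.psi + self.omega)


@dataclass
class FragmentLibrary:
    fragments: list[Fragment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fragments)

    def __eq__(self, other) -> bool:
        return isinstance(other, FragmentLibrary) and self.fragments == other.fragments

    @property
    def counts(self) -> dict[str, int]:
        c = {label: 0 for label in SS_LABELS}
        for fr in self.fragments:
            c[fr.ss_label] += 1
        return c


@dataclass
class PredictorConfig:
    """Settings for :func:`fit_fragment_predictor`.

    The cnn backend trains with Adam on mean-squared error, batch size 8,
    an 80/20 train/validation split and (by default) 200 epochs; angle
    targets are scaled to [-1, 1] by division by 180.
    """

    backend: str = "cnn"
    epochs: int = 200
    batch_size: int = 8
    learning_rate: float = 1e-3
    val_fraction: float = 0.2
    conv_channels: int = 32
    dropout: float = 0.1
    seed: int = 0


def split_windows(sequence) -> tuple[list[str], int]:
    """Consecutive non-overlapping six-residue windows and the remainder L mod 6."""
    seq = sequence.residues if isinstance(sequence, AminoAcidSequence) else str(sequence)
    n = len(seq) // WINDOW
    windows = [seq[k * WINDOW:(k + 1) * WINDOW] for k in range(n)]
    return windows, len(seq) % WINDOW


def generate_synthetic_library(n_alpha: int, n_beta: int, n_loop: int,
                               noise_deg: float = 5.0,
                               seed: int | None = 0) -> FragmentLibrary:
    """Seeded synthetic fragment library.

    Alpha fragments scatter around (phi, psi) = (-57, -47), beta around
    (-139, 135) with Gaussian noise of ``noise_deg`` (wrapped); loop
    fragments draw phi uniformly from a permissive band and psi uniformly
    over the circle.  Omega scatters around 180.  Sequences are uniform
    random six-mers, so a lookup predictor trained on such a library is
    exercised on realistic near-miss matches.
    """
    if min(n_alpha, n_beta, n_loop) < 0 or noise_deg < 0:
        raise DomainError("fragment counts and noise must be non-negative")
    if n_alpha + n_beta + n_loop == 0:
        raise DomainError("at least one fragment count must be positive")
    rng = np.random.default_rng(seed)
    fragments = []
    for label, count in (("alpha", n_alpha), ("beta", n_beta), ("loop", n_loop)):
        for _ in range(count):
            seq = "".join(rng.choice(list(AMINO_ACIDS), WINDOW))
            if label == "loop":
                phi = rng.uniform(*LOOP_PHI_RANGE, WINDOW)
                psi = rng.uniform(-180.0, 180.0, WINDOW)
            else:
                c = ALPHA_CENTER if label == "alpha" else BETA_CENTER
                phi = c[0] + rng.normal(0.0, noise_deg, WINDOW) if noise_deg else np.full(WINDOW, c[0])
                psi = c[1] + rng.normal(0.0, noise_deg, WINDOW) if noise_deg else np.full(WINDOW, c[1])
            omega = OMEGA_CENTER + (rng.normal(0.0, noise_deg, WINDOW) if noise_deg
                                    else np.zeros(WINDOW))
            fragments.append(Fragment(
                sequence=seq,
                phi=tuple(wrap_angles(phi)), psi=tuple(wrap_angles(psi)),
                omega=tuple(wrap_angles(omega)), ss_label=label))
    return FragmentLibrary(fragments=fragments)


def one_hot_encode(window: str) -> np.ndarray:
    """(6, 20) one-hot encoding in the canonical amino-acid order."""
    x = np.zeros((WINDOW, len(AMINO_ACIDS)))
    for i, ch in enumerate(window):
        x[i, AMINO_ACIDS.index(ch)] = 1.0
    return x


class LookupPredictor:
    """Deterministic retrieval backend.

    An exact window match returns that fragment's angles verbatim; otherwise
    the library is scanned for the fragment with the highest sequence
    identity, ties broken by library order (first wins).
    """

    backend = "lookup"

    def __init__(self, library: FragmentLibrary):
        if not len(library):
            raise DomainError("cannot build a predictor from an empty library")
        self.library = library
        self._exact = {}
        for fr in library.fragments:
            self._exact.setdefault(fr.sequence, fr)

    def predict(self, window: str) -> np.ndarray:
        fr = self._exact.get(window)
        if fr is None:
            best_score = -1
            for cand in self.library.fragments:
                score = sum(a == b for a, b in zip(cand.sequence, window))
                if score > best_score:
                    best_score, fr = score, cand
        return fr.angles()


class CNNPredictor:
    """Convolutional backend mapping a one-hot window to 18 scaled angles."""

    backend = "cnn"

    def __init__(self, net: TinyConvNet, validation_mse: float | None = None):
        self.net = net
        self.validation_mse = validation_mse

    def predict(self, window: str) -> np.ndarray:
        x = one_hot_encode(window)[None, :, :]
        return wrap_angles(self.net.predict(x)[0] * 180.0)

    def save(self, path) -> None:
        self.net.save(path)

    @classmethod
    def load(cls, path) -> "CNNPredictor":
        return cls(TinyConvNet.load(path))


def fit_fragment_predictor(library: FragmentLibrary,
                           config: PredictorConfig | None = None):
    """Train (cnn) or index (lookup) a fragment predictor on a library."""
    config = config or PredictorConfig()
    if not len(library):
        raise DomainError("cannot fit a predictor on an empty library")
    if config.backend == "lookup":
        return LookupPredictor(library)
    if config.backend != "cnn":
        raise DomainError(f"unknown predictor backend {config.backend!r}")
    if len(library) < 10:
        raise DomainError("cnn backend needs at least 10 fragments")
    rng = np.random.default_rng(config.seed)
    x = np.stack([one_hot_encode(fr.sequence) for fr in library.fragments])
    y = np.stack([fr.angles() for fr in library.fragments]) / 180.0
    order = rng.permutation(len(library))
    n_val = max(1, int(round(config.val_fraction * len(library))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if not len(train_idx):
        raise DomainError("library too small for the requested validation split")
    net = TinyConvNet(conv_channels=config.conv_channels,
                      dropout=config.dropout, seed=config.seed)
    xt, yt = x[train_idx], y[train_idx]
    for _ in range(config.epochs):
        perm = rng.permutation(len(xt))
        for start in range(0, len(xt), config.batch_size):
            batch = perm[start:start + config.batch_size]
            net.train_batch(xt[batch], yt[batch], config.learning_rate, rng)
    return CNNPredictor(net, validation_mse=net.mse(x[val_idx], y[val_idx]))


def predict_torsions(predictor, window: str):
    """(phi[6], psi[6], omega[6]) for one six-residue window, wrapped."""
    if len(window) != WINDOW:
        raise DomainError(f"prediction window must have {WINDOW} residues, "
                          f"got {len(window)}")
    out = wrap_angles(np.asarray(predictor.predict(window), dtype=float))
    if out.shape != (3 * WINDOW,):
        raise DomainError(f"predictor returned {out.shape}, expected ({3 * WINDOW},)")
    return out[0:6].copy(), out[6:12].copy(), out[12:18].copy()


def assemble_initial_state(sequence, predictor, rng_seed: int | None = 0,
                           topology=None) -> TorsionState:
    """Assemble the initial torsion state from per-window predictions.

    Residues covered by complete windows take predicted backbone angles;
    remainder residues get uniform random backbone angles, and every chi
    angle is drawn uniformly — the predictor's 18 outputs cover only the
    backbone.  Seeded and reproducible.
    """
    seq = sequence if isinstance(sequence, AminoAcidSequence) else AminoAcidSequence("seq", str(sequence))
    topology = topology or load_topology()
    rng = np.random.default_rng(rng_seed)
    n = len(seq)
    phi = np.empty(n); psi = np.empty(n); omega = np.empty(n)
    windows, remainder = split_windows(seq)
    for k, window in enumerate(windows):
        p, s, o = predict_torsions(predictor, window)
        sl = slice(k * WINDOW, (k + 1) * WINDOW)
        phi[sl], psi[sl], omega[sl] = p, s, o
    if remainder:
        sl = slice(n - remainder, n)
        phi[sl] = rng.uniform(-180.0, 180.0, remainder)
        psi[sl] = rng.uniform(-180.0, 180.0, remainder)
        omega[sl] = rng.uniform(-180.0, 180.0, remainder)
    chis = [rng.uniform(-180.0, 180.0, topology.residue(ch).chi_count)
            for ch in seq.residues]
    return TorsionState(seq, phi, psi, omega, chis)
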