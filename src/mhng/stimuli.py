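"""Color-stimulus generation in CIE-L*u*v* space.

The communication experiment uses two 15-item sets of colored patches, each
item a 3-vector (L*, u*, v*) drawn from one of three Gaussian components.
Dataset 1 ("hard") has overlapping components; Dataset 2 ("easy") has
well-separated ones.  Stimuli stay numeric — the analysis never needs
displayable colors, so no gamut clipping or sRGB conversion is done.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .random import derive_rng

__all__ = [
    "ColorGaussianSpec",
    "StimulusSet",
    "builtin_specs",
    "generate_dataset",
    "write_stimulus_csv",
    "read_stimulus_csv",
]


@dataclass(frozen=True)
class ColorGaussianSpec:
    """Three Gaussian components in L*u*v* sharing one covariance."""

    means: np.ndarray  # (3, 3)
    covariance: np.ndarray  # (3, 3), shared
    label: str

    def __post_init__(self):
        means = np.asarray(self.means, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if means.shape != (3, 3):
            raise ValueError(f"expected 3 three-dimensional means, got shape {means.shape}")
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ValueError("covariance must be a symmetric 3x3 matrix")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("covariance must be positive definite")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covariance", cov)


@dataclass
class StimulusSet:
    """Ordered color items with their generating component labels."""

    luv: np.ndarray  # (N, 3)
    component: np.ndarray  # (N,) ints in {0,1,2}
    dataset_label: str
    seed: int
    item_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.luv = np.asarray(self.luv, dtype=float)
        self.component = np.asarray(self.component, dtype=int)
        n = len(self.component)
        if self.luv.shape != (n, 3):
            raise ValueError("luv must be (N, 3)")
        if self.item_id is None:
            self.item_id = np.arange(n)
        self.item_id = np.asarray(self.item_id, dtype=int)
        if not np.array_equal(np.sort(self.item_id), np.arange(n)):
            raise ValueError("item_ids must be unique and contiguous from 0")
        if n and not np.isin(self.component, [0, 1, 2]).all():
            raise ValueError("component indices must lie in {0, 1, 2}")

    def __len__(self) -> int:
        return len(self.component)


def builtin_specs() -> tuple[ColorGaussianSpec, ColorGaussianSpec]:
    """The study's two stimulus configurations (hard, easy)."""
    hard = ColorGaussianSpec(
        means=np.array([[60.0, -10.0, 20.0], [60.0, -20.0, -10.0], [60.0, 20.0, 10.0]]),
        covariance=np.diag([5.0**2, 9.0**2, 9.0**2]),
        label="hard",
    )
    easy = ColorGaussianSpec(
        means=np.array([[60.0, 30.0, 30.0], [60.0, 30.0, -30.0], [60.0, -30.0, -30.0]]),
        covariance=np.diag([5.0**2, 10.0**2, 10.0**2]),
        label="easy",
    )
    return hard, easy


def get_spec(name: str) -> ColorGaussianSpec:
    hard, easy = builtin_specs()
    try:
        return {"hard": hard, "easy": easy}[name]
    except KeyError:
        raise ValueError(f"unknown dataset {name!r}; expected 'hard' or 'easy'") from None


def generate_dataset(
    spec: ColorGaussianSpec,
    n_items: int = 15,
    seed: int = 0,
    balanced: bool = False,
) -> StimulusSet:
    """Draw ``n_items`` color vectors from the three components of ``spec``.

    By default the component of each item is chosen uniformly at random;
    with ``balanced`` the components appear in equal counts (requires
    ``n_items`` divisible by 3) and are then shuffled.
    """
    if n_items < 1:
        raise ValueError("n_items must be positive")
    rng = derive_rng(seed, "stimuli", spec.label)
    if balanced:
        if n_items % 3:
            raise ValueError("balanced sets need n_items divisible by 3")
        component = np.repeat(np.arange(3), n_items // 3)
        rng.shuffle(component)
    else:
        component = rng.integers(0, 3, size=n_items)
    chol = np.linalg.cholesky(spec.covariance)
    noise = rng.standard_normal((n_items, 3))
    luv = spec.means[component] + noise @ chol.T
    return StimulusSet(luv=luv, component=component, dataset_label=spec.label, seed=seed)


_CSV_COLUMNS = ["item_id", "component", "L", "U", "V", "dataset_label", "seed"]


def write_stimulus_csv(stimuli: StimulusSet, path) -> None:
    df = pd.DataFrame(
        {
            "item_id": stimuli.item_id,
            "component": stimuli.component,
            "L": stimuli.luv[:, 0],
            "U": stimuli.luv[:, 1],
            "V": stimuli.luv[:, 2],
            "dataset_label": stimuli.dataset_label,
            "seed": stimuli.seed,
        }
    )
    df.to_csv(path, index=False)


def read_stimulus_csv(path) -> StimulusSet:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stimulus CSV missing columns: {sorted(missing)}")
    df = df.sort_values("item_id")
    return StimulusSet(
        luv=df[["L", "U", "V"]].to_numpy(float),
        component=df["component"].to_numpy(int),
        dataset_label=str(df["dataset_label"].iloc[0]),
        seed=int(df["seed"].iloc[0]),
        item_id=df["item_id"].to_numpy(int),
    )


def stimulus_csv_roundtrip_equal(a: StimulusSet, b: StimulusSet) -> bool:
    return (
        np.array_equal(a.item_id, b.item_id)
        and np.array_equal(a.component, b.component)
        and np.allclose(a.luv, b.luv)
        and a.dataset_label == b.dataset_label
        and a.seed == b.seed
    )
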