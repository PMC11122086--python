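"""Train and freeze the bundled synthetic BRISQUE regressor.

Builds a compact RBF support-vector regressor on simulated MR phantom slices
with graded blur/noise degradations and pseudo-quality labels (0 pristine,
rising with degradation severity), then writes it in the plain-text model
format that :func:`mriqa.nr_metrics.load_brisque_model` reads.  The bundled
file is a synthetic stand-in for an opinion-score-trained model: it fixes the
scoring direction (lower = better; blur and noise raise the score) rather
than reproducing any published score scale.

Usage:  python scripts/make_brisque_model.py [out_path]
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
from sklearn.svm import SVR

from mriqa.nr_metrics import brisque_features, load_brisque_model, brisque_score
from mriqa.phantom import Ellipsoid, PhantomSpec, apply_gaussian_blur, make_volume


def base_slices(n: int, seed: int) -> list[np.ndarray]:
    """Assorted clean textured phantom slices, 128x128."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        nz = 8
        compartments = []
        for _ in range(rng.integers(2, 5)):
            compartments.append(Ellipsoid(
                center=(nz / 2, float(rng.uniform(30, 98)), float(rng.uniform(30, 98))),
                radii=(nz, float(rng.uniform(12, 50)), float(rng.uniform(12, 50))),
                intensity=float(rng.uniform(80, 300)),
            ))
        spec = PhantomSpec(
            shape=(nz, 128, 128), n_timepoints=1, compartments=compartments,
            noise_sigma=0.0,
            texture_amplitude=float(rng.uniform(0.05, 0.25)),
            texture_scale_vox=float(rng.uniform(1.0, 4.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(make_volume(spec).slices[nz // 2].pixels)
    return out


def degraded(image: np.ndarray, blur: int, noise_frac: float,
             rng: np.random.Generator) -> np.ndarray:
    out = image
    if blur:
        out = apply_gaussian_blur(out, blur)
    if noise_frac:
        out = out + rng.normal(0, noise_frac * np.ptp(image), out.shape)
    return out


# (blur kernel or 0, noise fraction of range, pseudo-quality label)
CONDITIONS = [
    (0, 0.0, 5.0),
    (3, 0.0, 25.0), (5, 0.0, 40.0), (7, 0.0, 55.0), (11, 0.0, 70.0),
    (0, 0.02, 20.0), (0, 0.05, 35.0), (0, 0.10, 50.0), (0, 0.20, 70.0),
    (5, 0.05, 55.0), (7, 0.10, 75.0),
]


def main(out_path: Path) -> None:
    rng = np.random.default_rng(7)
    X, y = [], []
    for image in base_slices(22, seed=11):
        for blur, noise, label in CONDITIONS:
            X.append(brisque_features(degraded(image, blur, noise, rng)))
            y.append(label)
    X = np.asarray(X)
    y = np.asarray(y)

    fmin, fmax = X.min(axis=0), X.max(axis=0)
    span = np.where(fmax > fmin, fmax - fmin, 1.0)
    fmax = np.where(fmax > fmin, fmax, fmin + 1.0)
    Xs = -1.0 + 2.0 * (X - fmin) / span

    svr = SVR(kernel="rbf", C=100.0, gamma=0.05, epsilon=4.0)
    svr.fit(Xs, y)
    print(f"{len(y)} samples, {svr.support_.size} support vectors")

    sv_raw = X[svr.support_]
    lines = [
        "# Synthetic BRISQUE SVR model for mriqa.",
        "# Trained on simulated MR phantom slices with graded blur/noise",
        "# degradations and pseudo-quality labels; a stand-in for an",
        "# opinion-score-trained regressor. Lower scores mean better quality.",
        f"gamma {float(svr._gamma):.10g}",
        f"rho {float(-svr.intercept_[0]):.10g}",
        f"feature_min 1 36",
        " ".join(f"{v:.8g}" for v in fmin),
        f"feature_max 1 36",
        " ".join(f"{v:.8g}" for v in fmax),
        f"coefficients {svr.support_.size} 1",
    ]
    lines += [f"{c:.8g}" for c in svr.dual_coef_.ravel()]
    lines.append(f"support_vectors {svr.support_.size} 36")
    lines += [" ".join(f"{v:.8g}" for v in row) for row in sv_raw]
    out_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    print(f"wrote {out_path} ({out_path.stat().st_size} bytes)")

    # quick behavioural check on held-out slices
    model = load_brisque_model(out_path)
    check_rng = np.random.default_rng(99)
    ok = 0
    for image in base_slices(5, seed=1234):
        clean = brisque_score(brisque_features(image), model)
        blurred = brisque_score(brisque_features(apply_gaussian_blur(image, 7)), model)
        noisy = brisque_score(
            brisque_features(degraded(image, 0, 0.2, check_rng)), model)
        print(f"clean {clean:7.2f}  blurred {blurred:7.2f}  noisy {noisy:7.2f}")
        ok += (blurred > clean) and (noisy > clean)
    print(f"monotone on {ok}/5 held-out slices")


if __name__ == "__main__":
    target = Path(sys.argv[1]) if len(sys.argv) > 1 else (
        Path(__file__).resolve().parents[1]
        / "src" / "mriqa" / "data" / "brisque_svr_synthetic.txt")
    main(target)
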