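"""Reproducible study-scale experiments.

These compositions wire the generator, the interpolators and the decoding
pipeline into the three experiments the package's claims rest on:

* :func:`mixture_recovery` — can the trained network reach the generative
  noise floor on a fixture whose targets are known convex mixtures of the
  observed channels, and does it beat distance-weighted averaging?
* :func:`channel_count_trend` — does reconstruction error fall when the
  observed montage grows from 9 to 18 electrodes?
* :func:`density_classification` — does four-class motor-imagery decoding
  on the reconstructed 60-channel montage beat decoding on the 18 observed
  channels, and approach decoding on the true 60 channels?

Every experiment is deterministic given its seed and returns plain floats,
so the same entry points serve the test suite and the reproduction script.
Problem sizes (recording lengths, trial counts, network width and training
length) are fixed here as the package's reference desk-scale conditions.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .bilstm import TrainConfig, predict_series, reconstruct_epochs, train
from .classical_interp import IDWConfig, idw_predict_series, spline_predict_series
from .evaluation import ClassifyConfig, compare_densities, rmse
from .montage import ChannelSplit, builtin_split, load_builtin_montage
from .preprocess import Recording, concatenate_epochs, split_rounds
from .synth import SynthConfig, generate_mi_epochs, generate_recording, make_linear_mixture_case

__all__ = [
    "mixture_recovery",
    "channel_count_trend",
    "density_classification",
    "vertex_baseline_comparison",
]


def _segment(rec: Recording, lo_s: float, hi_s: float) -> Recording:
    lo, hi = int(lo_s * rec.fs), int(hi_s * rec.fs)
    return Recording(data=rec.data[:, lo:hi], fs=rec.fs,
                     channel_labels=rec.channel_labels)


def mixture_recovery(seed: int, duration_s: float = 60.0, noise_sd: float = 0.1,
                     n_targets: int = 4, train_cfg: TrainConfig | None = None,
                     ) -> dict:
    """Parameter recovery on the linear-mixture fixture (18 observed).

    The recording splits 40/10/10 s into train/validation/test.  Returns the
    mean test RMSE of the trained network, of both IDW variants and of the
    line-spline baseline where a line exists, plus the generative noise
    floor.  All RMSEs in microvolts.
    """
    montage = load_builtin_montage()
    s18 = builtin_split(18, montage)
    split = ChannelSplit(observed=s18.observed,
                         targets=tuple(sorted(s18.targets)[:n_targets]))
    rec, _ = make_linear_mixture_case(montage, split, mix_seed=seed,
                                      noise_sd=noise_sd, duration_s=duration_s)
    t1, t2 = duration_s * 2 / 3, duration_s * 5 / 6
    tr = _segment(rec, 0, t1)
    va = _segment(rec, t1, t2)
    te = _segment(rec, t2, duration_s)
    if train_cfg is None:
        train_cfg = TrainConfig(batch_size=100, seq_len=120, stride=20,
                                hidden1=32, hidden2=32, learning_rate=1e-2,
                                max_epochs=200, patience=200, seed=seed)
    net = train(tr, va, split, montage, train_cfg)
    truth = te.data[split.targets_idx0]
    pred = predict_series(net, te, split)
    out = {
        "bilstm_rmse": float(np.mean([rmse(pred[i], truth[i])
                                      for i in range(len(truth))])),
        "noise_floor": noise_sd,
    }
    for power in (1, 2):
        idw = idw_predict_series(te, split, montage, IDWConfig(power=power))
        out[f"idw_rmse_p{power}"] = float(np.mean([
            rmse(idw[i], truth[i]) for i in range(len(truth))
        ]))
    spline_errs = []
    for i, tgt in enumerate(split.targets):
        try:
            sp = spline_predict_series(te, split, montage, target_index=tgt)
        except ValueError:
            continue  # no usable electrode line for this target
        spline_errs.append(rmse(sp, truth[i]))
    if spline_errs:
        out["spline_rmse"] = float(np.mean(spline_errs))
    return out


def vertex_baseline_comparison(seed: int, duration_s: float = 20.0) -> dict:
    """Classical baselines predicting the vertex electrode (Cz, channel 31).

    On a synthetic recording, Cz is reconstructed from the observed central
    row (C5, C3, C1, C2, C4, C6) by the line spline and by both IDW
    variants over the full 18-electrode set extended with the central row.
    Returns RMSEs in microvolts.
    """
    montage = load_builtin_montage()
    labels = ["Fp1", "Fp2", "F7", "F8", "F3", "Fz", "F4",
              "C5", "C3", "C1", "C2", "C4", "C6",
              "CP3", "CPz", "CP4", "P3", "Pz", "P4", "O1", "O2"]
    split = ChannelSplit.from_labels(montage, labels)
    rec = generate_recording(montage, SynthConfig(seed=seed), duration_s)
    cz = montage.index_of("Cz")
    truth = rec.data[cz - 1]
    spline = spline_predict_series(rec, split, montage, target_index=cz)
    out = {"spline_rmse_cz": rmse(spline, truth)}
    tgt_order = list(split.targets)
    idx = tgt_order.index(cz)
    for power in (1, 2):
        idw = idw_predict_series(rec, split, montage, IDWConfig(power=power))
        out[f"idw_rmse_cz_p{power}"] = rmse(idw[idx], truth)
    return out


def channel_count_trend(seed: int, duration_s: float = 30.0,
                        max_epochs: int = 80) -> dict:
    """Reconstruction error of the same target set from 9 vs 18 electrodes.

    Both conditions predict the 42 channels unobserved by the 18-electrode
    montage (the 9-electrode set is a subset of the 18-electrode set), on
    identical synthetic data from the spatial mixing model.
    """
    montage = load_builtin_montage()
    s18 = builtin_split(18, montage)
    rec = generate_recording(montage, SynthConfig(seed=seed), duration_s)
    t1, t2 = duration_s * 2 / 3, duration_s * 5 / 6
    tr = _segment(rec, 0, t1)
    va = _segment(rec, t1, t2)
    te = _segment(rec, t2, duration_s)
    out = {}
    for n_obs in (9, 18):
        observed = builtin_split(n_obs, montage).observed
        split = ChannelSplit(observed=observed, targets=s18.targets)
        cfg = TrainConfig(batch_size=100, seq_len=120, stride=40,
                          hidden1=24, hidden2=24, learning_rate=1e-2,
                          max_epochs=max_epochs, patience=max_epochs, seed=seed)
        net = train(tr, va, split, montage, cfg)
        pred = predict_series(net, te, split)
        truth = te.data[split.targets_idx0]
        out[f"rmse_{n_obs}ch"] = float(np.mean([
            rmse(pred[i], truth[i]) for i in range(len(truth))
        ]))
    return out


def _fit_fold_network(train_epochs, split, montage, cfg: TrainConfig):
    """Train on the concatenated training trials, validating on the tail."""
    rec = concatenate_epochs(train_epochs)
    n_val = int(rec.n_samples * 0.15)
    n_val -= n_val % cfg.seq_len  # keep windows trial-aligned
    tr = Recording(data=rec.data[:, :-n_val], fs=rec.fs,
                   channel_labels=rec.channel_labels)
    va = Recording(data=rec.data[:, -n_val:], fs=rec.fs,
                   channel_labels=rec.channel_labels)
    return train(tr, va, split, montage, cfg)


def density_classification(seed: int, n_trials_per_class: int = 50,
                           erd_depth: float = 0.5, max_epochs: int = 20,
                           synth_cfg: SynthConfig | None = None,
                           classify_cfg: ClassifyConfig | None = None) -> dict:
    """The central downstream comparison, on synthetic motor imagery.

    For each of the five round-folds, the interpolator is trained on the
    eight training rounds' full 60-channel trials, the test rounds' trials
    are reconstructed from their 18 observed channels, and the identical
    band-pass + CSP + OVR decoder is cross-validated on (a) the 18 observed
    channels, (b) the reconstructed 60 channels and (c) the true 60
    channels.  A label-shuffled control on the true channels estimates the
    chance level.  The interpolator is trained on the decoder's frequency
    band, where reconstruction fidelity matters.  Returns total accuracies
    as fractions.
    """
    montage = load_builtin_montage()
    split = builtin_split(18, montage)
    if synth_cfg is None:
        synth_cfg = SynthConfig(seed=seed, erd_depth=erd_depth)
    if classify_cfg is None:
        classify_cfg = ClassifyConfig()
    epochs = generate_mi_epochs(montage, synth_cfg, n_trials_per_class)

    from .preprocess import bandpass_array

    banded = replace(epochs, data=bandpass_array(
        epochs.data, classify_cfg.band[0], classify_cfg.band[1], epochs.fs
    ))

    # fold-wise reconstruction of the test trials (no leakage across rounds)
    recon = banded.data.copy()
    base_cfg = TrainConfig(batch_size=100, seq_len=150, hidden1=16, hidden2=16,
                           learning_rate=1e-2, max_epochs=max_epochs,
                           patience=max(5, max_epochs), seed=seed)
    for fold in range(1, classify_cfg.n_folds + 1):
        train_e, test_e = split_rounds(banded, fold)
        net = _fit_fold_network(train_e, split, montage,
                                replace(base_cfg, seed=seed + fold))
        rebuilt = reconstruct_epochs(net, test_e, split)
        is_test = np.isin(banded.round_ids, [2 * fold - 1, 2 * fold])
        recon[is_test] = rebuilt.data
    epochs_pred = replace(banded, data=recon)
    epochs_low = epochs.pick(split.observed_idx0)

    results = compare_densities(
        {"18ch": epochs_low, "bilstm60": epochs_pred, "true60": epochs},
        classify_cfg,
    )
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5F]))
    shuffled = replace(epochs, labels=shuffle_rng.permutation(epochs.labels))
    chance = compare_densities({"shuffled": shuffled}, classify_cfg)
    return {
        "acc_18ch": results["18ch"]["total"],
        "acc_bilstm60": results["bilstm60"]["total"],
        "acc_true60": results["true60"]["total"],
        "acc_shuffled": chance["shuffled"]["total"],
        "per_class": {k: results[k]["per_class"] for k in results},
        "n_trials": int(epochs.n_trials),
    }
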