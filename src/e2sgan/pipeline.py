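"""End-to-end orchestration of the two-stage pipeline.

Stage one prepares aligned data: synthesize (or ingest) paired recordings,
filter/resample/segment them, match scalp to depth channels, and encode the
matched pair as spectral tensors. Stage two trains the translation network
on the aligned tensors, evaluates the synthesis against the scalp baseline,
and runs the band-perturbation analysis. Every stage writes its artifacts
under the run directory and records completion in a manifest, so a
re-executed pipeline skips finished stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .config import PipelineConfig
from .evaluation import evaluate_segments
from .matching import match_channels
from .model import Generator
from .perturbation import perturbation_correlation, run_perturbation
from .preprocess import preprocess_recording, segment_recording
from .spectral import SpectralTensor, fit_norm_params, invert_features, stft_features
from .synthetic import SourceModel, make_paired_recording
from .training import train

STAGES = ("synth", "preprocess", "match", "spectra", "train", "eval", "perturb")


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class Pipeline:
    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
            if self.manifest.get("config_hash") != _config_hash(cfg):
                raise RuntimeError(
                    "run directory was produced with a different configuration; "
                    "use a fresh --out directory")
        else:
            self.manifest = {"config_hash": _config_hash(cfg),
                             "seed": cfg.seed, "done": []}

    def _mark(self, stage: str):
        if stage not in self.manifest["done"]:
            self.manifest["done"].append(stage)
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def _skip(self, stage: str) -> bool:
        return stage in self.manifest["done"]

    # -- stages ------------------------------------------------------------

    def synth(self):
        if self._skip("synth"):
            return
        c = self.cfg.synth
        model = SourceModel(noise_sd=c.noise_sd, burst_rate=c.burst_rate,
                            attenuation_exponent=c.attenuation_exponent,
                            seed=self.cfg.seed)
        rec = make_paired_recording(model, c.n_eeg, c.n_seeg, c.duration_s,
                                    c.rate_hz)
        eio.write_recording(self.out / "eeg.npz", rec.eeg)
        eio.write_recording(self.out / "seeg.npz", rec.seeg)
        coords = dict(rec.eeg.coords)
        coords.update(rec.seeg.coords)
        eio.write_coords_tsv(self.out / "coords.tsv", coords)
        (self.out / "truth_pairs.json").write_text(json.dumps(rec.truth_pairs))
        self._mark("synth")

    def preprocess(self):
        if self._skip("preprocess"):
            return
        f = self.cfg.filter
        for kind in ("eeg", "seeg"):
            rec = eio.read_recording(self.out / f"{kind}.npz")
            out = preprocess_recording(rec, kind, line_hz=f.line_hz,
                                       target_hz=f.target_hz)
            eio.write_recording(self.out / f"{kind}_preproc.npz", out)
        self._mark("preprocess")

    def _segments(self):
        sp = self.cfg.spectral
        eeg = eio.read_recording(self.out / "eeg_preproc.npz")
        seeg = eio.read_recording(self.out / "seeg_preproc.npz")
        return (segment_recording(eeg, win=sp.segment, stride=sp.stride),
                segment_recording(seeg, win=sp.segment, stride=sp.stride))

    def match(self):
        if self._skip("match"):
            return
        eeg_segs, seeg_segs = self._segments()
        coords = eio.read_coords_tsv(self.out / "coords.tsv")
        res = match_channels(eeg_segs, seeg_segs, coords,
                             rate=self.cfg.filter.target_hz,
                             bin_mm=self.cfg.match.bin_mm)
        (self.out / "match.json").write_text(json.dumps({
            "itv_star": res.itv_star,
            "pairs": res.pairs,
            "intervals": [
                {"low": iv.low, "high": iv.high, "n_pairs": iv.n_pairs,
                 "positive_fraction": iv.positive_fraction,
                 "mean_slope": iv.mean_slope}
                for iv in res.per_interval],
        }, indent=2))
        self._mark("match")

    def spectra(self):
        if self._skip("spectra"):
            return
        sp = self.cfg.spectral
        pairs = json.loads((self.out / "match.json").read_text())["pairs"]
        e_ch, s_ch = pairs[0]
        eeg_segs, seeg_segs = self._segments()
        e_m = eeg_segs[e_ch].segments
        s_m = seeg_segs[s_ch].segments
        n_eval = max(2, len(e_m) // 8)
        n_train = len(e_m) - n_eval
        norm_e = fit_norm_params(e_m[:n_train], sp.window, sp.hop)
        norm_s = fit_norm_params(s_m[:n_train], sp.window, sp.hop)
        rate = self.cfg.filter.target_hz

        def encode(mat, norm):
            ts = [stft_features(x, sp.window, sp.hop, rate, norm) for x in mat]
            return (np.clip(np.stack([t.array for t in ts]), -1, 1),
                    np.stack([t.anchor_phase for t in ts]))

        e_arr, e_anchor = encode(e_m, norm_e)
        s_arr, _ = encode(s_m, norm_s)
        np.savez_compressed(self.out / "tensors.npz", e=e_arr, s=s_arr,
                            e_anchor=e_anchor, e_seg=e_m, s_seg=s_m,
                            n_train=n_train)
        (self.out / "norm.json").write_text(json.dumps({
            "pair": [e_ch, s_ch],
            "eeg": asdict(norm_e), "seeg": asdict(norm_s)}))
        self._mark("spectra")

    def train(self):
        if self._skip("train"):
            return
        with np.load(self.out / "tensors.npz") as f:
            e_arr, s_arr, n_train = f["e"], f["s"], int(f["n_train"])
        cfg = self.cfg.training
        gen, disc, history = train(
            e_arr[:n_train], s_arr[:n_train], cfg, self.cfg.model,
            val=(e_arr[n_train:], s_arr[n_train:]))
        np.savez_compressed(self.out / "generator.npz",
                            *gen.state_dict())
        pd.DataFrame(history.steps).to_csv(self.out / "train_log.csv",
                                           index=False)
        self._mark("train")

    def _load_generator(self) -> Generator:
        gen = Generator(self.cfg.model, seed=self.cfg.training.seed)
        with np.load(self.out / "generator.npz") as f:
            gen.load_state_dict([f[k] for k in f.files])
        return gen

    def _fake_tensor(self, out_arr, anchor, norm_s) -> SpectralTensor:
        sp = self.cfg.spectral
        return SpectralTensor(mag=out_arr[0], ifreq=out_arr[1], norm=norm_s,
                              anchor_phase=anchor, window=sp.window,
                              hop=sp.hop, rate=self.cfg.filter.target_hz)

    def _norms(self):
        from .spectral import NormParams
        meta = json.loads((self.out / "norm.json").read_text())
        return NormParams(**meta["eeg"]), NormParams(**meta["seeg"])

    def eval(self):
        if self._skip("eval"):
            return
        gen = self._load_generator()
        _, norm_s = self._norms()
        with np.load(self.out / "tensors.npz") as f:
            e_arr, anchors = f["e"], f["e_anchor"]
            e_seg, s_seg, n_train = f["e_seg"], f["s_seg"], int(f["n_train"])
        fakes = []
        for i in range(n_train, e_arr.shape[0]):
            out = gen(e_arr[i]).data
            fakes.append(invert_features(
                self._fake_tensor(out, anchors[i], norm_s)))
        report = evaluate_segments(np.stack(fakes), s_seg[n_train:],
                                   e_seg[n_train:],
                                   rate=self.cfg.filter.target_hz,
                                   nperseg=self.cfg.eval.nperseg)
        report.table.to_csv(self.out / "eval_raw.csv")
        report.log_table.to_csv(self.out / "eval_log.csv")
        (self.out / "eval_summary.json").write_text(json.dumps({
            "baselines": report.baselines,
            "aggregate": {m: {"mean": float(report.aggregate.loc[m, "mean"]),
                              "std": float(report.aggregate.loc[m, "std"])}
                          for m in report.aggregate.index}}, indent=2))
        self._mark("eval")

    def perturb(self):
        if self._skip("perturb"):
            return
        gen = self._load_generator()
        norm_e, norm_s = self._norms()
        sp = self.cfg.spectral
        rate = self.cfg.filter.target_hz
        pair = json.loads((self.out / "norm.json").read_text())["pair"]
        with np.load(self.out / "tensors.npz") as f:
            e_seg, s_seg, n_train = f["e_seg"], f["s_seg"], int(f["n_train"])

        def generate(t: SpectralTensor) -> SpectralTensor:
            out = gen(t.array).data
            return self._fake_tensor(out, t.anchor_phase, norm_s)

        inputs = {pair[0]: [
            (stft_features(e_seg[i], sp.window, sp.hop, rate, norm_e),
             s_seg[i])
            for i in range(n_train, min(n_train + 2, e_seg.shape[0]))
        ]}
        runs = run_perturbation(generate, inputs, rate,
                                repeats=self.cfg.perturb.repeats,
                                seed=self.cfg.seed)
        runs.to_csv(self.out / "perturb_runs.csv", index=False)
        perturbation_correlation(runs).to_csv(
            self.out / "perturb_correlation.csv", index=False)
        self._mark("perturb")

    def run(self):
        for stage in STAGES:
            getattr(self, stage)()
        return self.out


def run_pipeline(cfg: PipelineConfig) -> Path:
    return Pipeline(cfg).run()
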