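"""End-to-end pipeline: corpus -> networks -> simulated trials -> analyses.

Drives every stage from one :class:`~mirrorgame.config.RunConfig` and its
master seed, writing all artifacts under an output directory and returning
one per-trial report table.  Re-running with the same config is
reproducible.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .controller import run_agent
from .coordination import leader_follower_ratio, mean_abs_lag, wtlcc
from .evaluation import sensitivity_matrix
from .follow_net import make_windows, train_follow
from .io import save_corpus_h5, write_manifest
from .kinematics import filter_trajectory, speed_profile, trial_kinematics
from .lead_net import generate_sequence, sample_seed_chunk, train_lead
from .synthetic import generate_dyad_corpus, splitmix64

__all__ = ["run_end_to_end", "trial_wtlcc"]


def trial_wtlcc(track1: np.ndarray, track2: np.ndarray, rate: float, config: RunConfig):
    """WTLCC of two hand tracks: filter, take speeds, correlate windows."""
    s1 = speed_profile(filter_trajectory(track1, rate)).speed
    s2 = speed_profile(filter_trajectory(track2, rate)).speed
    return wtlcc(
        s1,
        s2,
        window=config.wtlcc_window,
        step=config.wtlcc_step,
        max_lag=config.wtlcc_max_lag,
        rate=rate,
    )


def run_end_to_end(config: RunConfig, outdir: str | Path, log=print) -> pd.DataFrame:
    """Generate, train, simulate and analyze; returns the report table.

    Stages: synthetic corpus -> follow-net and lead-net training -> one
    simulated agent trial per mode (lead / follow / improvise) against a
    fresh partner -> kinematic, WTLCC and sensitivity analyses.  All
    artifacts (corpus, manifest, models, traces, report, sensitivity
    matrix) land under *outdir*.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    def stage(msg: str) -> None:
        log(f"[{time.perf_counter() - t0:7.1f}s] {msg}")

    syn = config.synthesis()
    stage("generating dyad corpus")
    corpus = generate_dyad_corpus(syn, config.n_trials, duration=config.trial_duration_s)
    save_corpus_h5(corpus, outdir / "corpus.h5")
    write_manifest(corpus, outdir / "manifest.csv")

    stage("training follow-net")
    fcfg = config.follow()
    follow_model, follow_losses = train_follow(corpus, fcfg, seed=config.seed_for("follow"))
    follow_model.save(outdir / "follow_net.npz")

    stage("training lead-net")
    lcfg = config.lead()
    leaders = [t.leader for t in corpus if t.condition != "improvise"]
    lead_model, lead_losses = train_lead(leaders, lcfg, seed=config.seed_for("lead"))
    lead_model.save(outdir / "lead_net.npz")

    stage("generating lead sequence")
    chunk = sample_seed_chunk(leaders, lcfg, seed=config.seed_for("chunk"))
    lead_seq = generate_sequence(lead_model, chunk, lcfg)

    rows = []
    for mode_i, mode in enumerate(("lead", "follow", "improvise")):
        stage(f"simulating agent in {mode} mode")
        partner = corpus[0].leader  # a representative human-side sequence
        agent, trace = run_agent(
            partner,
            mode,
            follow_model,
            lead_seq,
            seed=splitmix64(config.seed_for("simulate"), mode_i),
            follow_config=fcfg,
        )
        trace.to_csv(outdir / f"trace_{mode}.csv", index=False)
        res = trial_wtlcc(agent.hand_track, partner.hand_track, agent.rate, config)
        from .kinematics import dyad_kinematics

        dk = dyad_kinematics(
            filter_trajectory(agent.hand_track, agent.rate),
            filter_trajectory(partner.hand_track, agent.rate),
        )
        rows.append(
            {
                "mode": mode,
                "n_windows": res.n_windows,
                "t_hat_frames": mean_abs_lag(res),
                "t_hat_ms": mean_abs_lag(res) / agent.rate * 1000.0,
                "r_LF_pct": leader_follower_ratio(res),
                "v_bar_agent": dk.player1.v_bar,
                "v_bar_partner": dk.player2.v_bar,
                "delta_v_bar": dk.delta_v_bar,
                "delta_a_bar": dk.delta_a_bar,
                "d_bar": dk.d_bar,
                "follow_final_loss": follow_losses[-1],
                "lead_final_loss": lead_losses[-1],
            }
        )

    stage("sensitivity analysis")
    lead_trial = next(t for t in corpus if t.condition != "improvise")
    X, _ = make_windows(lead_trial.leader, lead_trial.follower, fcfg)
    n_seq = min(50, X.shape[0])
    sens = sensitivity_matrix(
        follow_model, X, n_sequences=n_seq, n_replacements=3,
        seed=config.seed_for("sensitivity"), config=fcfg, joints=fcfg.joints,
    )
    sens.to_dataframe().to_csv(outdir / "sensitivity.csv")

    report = pd.DataFrame(rows)
    report.to_csv(outdir / "report.csv", index=False)
    stage("done")
    return report
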