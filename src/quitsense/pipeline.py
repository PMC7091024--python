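"""End-to-end pipeline: simulate -> decide -> analyze, with provenance.

Every run writes a provenance JSON carrying the effective configuration,
the seed, the package version, and SHA-256 checksums of every output file;
re-running with the same configuration reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, dump_config
from .ema import PROMPTS_PER_DAY, EmaResponse, read_ema_csv
from .engine import (
    Decision,
    EngagementEvent,
    MessageBank,
    decide_responses,
    read_decisions_jsonl,
    write_decisions_jsonl,
)
from .errors import QuitsenseError
from .simulate import TrialDataset, simulate_trial
from .stats import abstinence_table, chisq_independence, compensation, message_distribution

logger = logging.getLogger("quitsense")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def analyze(
    responses: Sequence[EmaResponse],
    visit_rows: Sequence[Mapping],
    decisions: Sequence[Mapping],
    arms: Sequence[str] = ("smart_t2", "quitguide", "usual_care"),
    scheduled_per_participant: Optional[Mapping[str, int]] = None,
) -> dict:
    """The trial report: abstinence tables + chi-square per follow-up visit,
    per-participant compensation, compliance, and message distributions.

    ``scheduled_per_participant`` supplies each participant's number of
    scheduled prompted EMAs (the compliance denominator, excluding
    post-dropout prompts); without it the full 5-per-day schedule of 175 is
    assumed for everyone.
    """
    warnings: list[dict] = []
    report: dict = {"n_participants": 0, "warnings": warnings}

    ema_df = pd.DataFrame(
        {
            "participant_id": r.participant_id,
            "arm": r.arm,
            "initiation": r.initiation,
        }
        for r in responses
    )
    pids = (
        ema_df[["participant_id", "arm"]].drop_duplicates("participant_id")
        if len(ema_df)
        else pd.DataFrame(columns=["participant_id", "arm"])
    )
    report["n_participants"] = int(len(pids))

    # --- abstinence ---
    report["abstinence"] = {}
    for visit in ("quit_date", "week4", "week12"):
        table = abstinence_table(visit_rows, visit, arms=arms)
        entry: dict = dict(table)
        cells = [[a, n - a] for a, n in (table["per_arm"][arm] for arm in arms)]
        try:
            stat, df, p = chisq_independence(cells)
            entry["chi_square"] = {"statistic": stat, "df": df, "p": p}
        except QuitsenseError as exc:
            entry["chi_square"] = None
            warnings.append({"stage": "analyze", "visit": visit, "message": str(exc)})
        entry["per_arm"] = {k: list(v) for k, v in table["per_arm"].items()}
        report["abstinence"][visit] = entry

    # --- compliance & compensation ---
    full_schedule = PROMPTS_PER_DAY * 35
    completed = (
        ema_df[ema_df["initiation"] == "prompted"].groupby("participant_id").size()
        if len(ema_df)
        else pd.Series(dtype=int)
    )
    attended = {
        (str(r["participant_id"]), r["visit"]): bool(r["attended"])
        for r in visit_rows
        if "attended" in r
    }
    comp = {}
    total_completed = 0
    total_scheduled = 0
    for _, row in pids.iterrows():
        pid = str(row["participant_id"])
        n_completed = int(completed.get(pid, 0))
        n_scheduled = (
            int(scheduled_per_participant.get(pid, full_schedule))
            if scheduled_per_participant
            else full_schedule
        )
        visits_flags = [
            True,  # baseline visit: attended by every randomized participant
            attended.get((pid, "quit_date"), False),
            attended.get((pid, "week4"), False),
            attended.get((pid, "week12"), False),
        ]
        comp[pid] = {
            "completed": n_completed,
            "scheduled": n_scheduled,
            "percent": round(100.0 * n_completed / n_scheduled, 1) if n_scheduled else None,
            "usd": compensation(n_completed, n_scheduled, visits_flags),
        }
        total_completed += n_completed
        total_scheduled += n_scheduled
    report["compensation"] = comp
    report["compliance"] = {
        "completed": total_completed,
        "scheduled": total_scheduled,
        "rate": total_completed / total_scheduled if total_scheduled else None,
    }

    # --- messages ---
    report["messages"] = message_distribution(decisions)
    return report


def run_pipeline(config: RunConfig, out_dir) -> dict[str, Path]:
    """simulate -> decide -> analyze; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage=simulate seed=%d", config.seed)
    try:
        dataset: TrialDataset = simulate_trial(
            config.sim_config(),
            arms=config.arms,
            calendar=config.calendar,
            window=config.window,
            risk_config=config.risk,
        )
        paths = dataset.write(out)
    except Exception as exc:
        raise QuitsenseError(f"simulate stage failed: {exc}") from exc

    logger.info("stage=decide")
    try:
        bank = MessageBank.from_json(config.bank_path) if config.bank_path else MessageBank.default()
        decisions = decide_responses(
            dataset.responses(), bank, config.risk, config.calendar, arm_filter="smart_t2"
        )
        paths["decisions"] = out / "decisions.jsonl"
        write_decisions_jsonl(decisions, paths["decisions"])
        _append_gum_events(paths["events"], decisions, config)
    except Exception as exc:
        raise QuitsenseError(f"decide stage failed: {exc}") from exc

    logger.info("stage=analyze")
    try:
        scheduled = {p.participant_id: p.n_scheduled for p in dataset.participants}
        report = analyze(
            dataset.responses(),
            dataset.visit_rows(),
            [d.to_record() for d in decisions],
            arms=config.arms,
            scheduled_per_participant=scheduled,
        )
        paths["report"] = out / "report.json"
        with open(paths["report"], "w") as fh:
            json.dump(_round_floats(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
    except QuitsenseError:
        raise
    except Exception as exc:
        raise QuitsenseError(f"analyze stage failed: {exc}") from exc

    provenance = {
        "package": "quitsense",
        "version": __version__,
        "seed": config.seed,
        "config": dump_config(config),
        "checksums": {name: _sha256(p) for name, p in sorted(paths.items())},
    }
    prov_path = out / "provenance.json"
    with open(prov_path, "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["provenance"] = prov_path
    return paths


def _append_gum_events(events_path: Path, decisions: Sequence[Decision], config: RunConfig) -> None:
    """Simulated yes/no answers to each gum prompt (own seed stream)."""
    sim = config.sim_config()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    with open(events_path, "a") as fh:
        for d in decisions:
            if not d.gum_prompt:
                continue
            kind = "gum_yes" if rng.random() < sim.p_gum_yes else "gum_no"
            event = EngagementEvent(
                participant_id=d.participant_id, kind=kind, day=d.day, at=min(d.time, 1439)
            )
            fh.write(json.dumps(event.model_dump()) + "\n")


def analyze_files(ema_path, visits_path, decisions_path, out_path=None) -> dict:
    """File-based variant of :func:`analyze` used by the command line."""
    responses = read_ema_csv(ema_path)
    visits = pd.read_csv(visits_path).to_dict("records")
    decisions = read_decisions_jsonl(decisions_path) if decisions_path else []
    report = analyze(responses, visits, decisions)
    if out_path:
        with open(out_path, "w") as fh:
            json.dump(_round_floats(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
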