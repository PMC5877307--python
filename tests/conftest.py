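import dataclasses

import pytest

import sedmine as sm


@pytest.fixture(scope="session")
def sim_cfg() -> sm.SimConfig:
    return sm.SimConfig(seed=42)


@pytest.fixture(scope="session")
def run_cfg() -> sm.RunConfig:
    return sm.RunConfig(seed=42, sim=sm.SimConfig(seed=42))


@pytest.fixture(scope="session")
def trained(run_cfg):
    """Motion + audio stores trained on the default synthetic trials."""
    sched = sm.default_training_schedule()
    accel, audio, _ = sm.simulate_day(sched, run_cfg.sim)
    return sm.train_from_recordings(
        accel, audio, sm.schedule_annotations(sched), run_cfg
    )


@pytest.fixture(scope="session")
def still_hour_timeline(run_cfg, trained):
    """Inference over a 60-minute continuously still (tv) simulation."""
    day_cfg = dataclasses.replace(run_cfg.sim, seed=run_cfg.sim.seed + 7)
    schedule = sm.Schedule(entries=[sm.ScheduleEntry("still_tv", 3600)])
    accel, audio, _ = sm.simulate_day(schedule, day_cfg)
    return sm.run_timeline(
        accel, audio, trained.motion_store, trained.audio_store,
        run_cfg.engine_config(),
    )


def make_timeline(motion_labels, micros=None, start_s=0.0):
    """Build a timeline from a string/list like 'ssssaass' (s=still, a=active)."""
    records = []
    for i, m in enumerate(motion_labels):
        motion = "still" if m in ("s", "still") else "active"
        if motion == "active":
            micro = "none"
        elif micros is not None:
            micro = micros[i]
        else:
            micro = "unknown"
        records.append(
            sm.EpochRecord(
                minute_start_s=start_s + 60.0 * i,
                motion=motion,
                micro=micro,
                audio_sampled=False,
            )
        )
    return sm.EpochTimeline(records=records)
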