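"""Simulate a study-shaped dataset and write the raw plain-text layout.

A desk-scale study (20 subjects x 8 videos of 6-9 s) with two appraisal
items driven by physiological latents — pleasantness by the zygomaticus
amplitude (saturating link) and suddenness by the same latent through a
threshold link — plus one pure-noise item.  Writes results/raw/ and prints
where the ground truth lives.
"""

from pathlib import Path

from physioappraisal import EffectSpec, StudyConfig, generate_study
from physioappraisal.io import write_dataset

OUT = Path("results")
SEED = 1


def config() -> StudyConfig:
    return StudyConfig(
        n_subjects=20,
        n_videos=8,
        video_duration_s=(6.0, 9.0),
        baseline_duration_s=8.0,
        effect_spec=(
            EffectSpec("pleasantness", "zygomaticus_amplitude", "saturating", 1, 1.0),
            EffectSpec("suddenness", "zygomaticus_amplitude", "threshold", 1, 1.0),
        ),
        items=("pleasantness", "suddenness", "familiarity"),
        missing_rate=0.05,
        noise_sd=0.1,
        seed=SEED,
    )


def main() -> None:
    dataset = generate_study(config(), include_streams=True)
    write_dataset(dataset, OUT / "raw")
    dataset.truth.latents.to_csv(OUT / "true_latents.csv", index=False)
    print(f"simulated {len(dataset.recordings)} recordings "
          f"({len(dataset.baselines)} subjects x {config().n_videos} videos)")
    print(f"raw layout -> {OUT / 'raw'}; ground-truth latents -> {OUT / 'true_latents.csv'}")


if __name__ == "__main__":
    main()
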