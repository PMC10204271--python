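"""The default simulated study the analysis scripts share.

Four occipito-frontal regions, four sites each, 16 spontaneous eye
closures/openings.  Injected modulations follow the qualitative pattern of
posterior-dominant-rhythm reactivity: proactive alpha augmentation in the
lateral occipital regions and the left posterior inferior frontal gyrus
around eye closure with concurrent high-gamma attenuation, and the mirror
pattern (alpha attenuation, high-gamma augmentation) after eye opening.
"""

from dyntract.synth import ModulationProfile, SimConfig


def scenario(seed: int = 0) -> SimConfig:
    profiles = [
        ModulationProfile("lateral_occipital_L", "alpha", "closure_onset", -75.0, 1500.0, 50.0),
        ModulationProfile("lateral_occipital_R", "alpha", "closure_onset", -75.0, 1500.0, 45.0),
        ModulationProfile("pIFG_L", "alpha", "closure_onset", -50.0, 1200.0, 35.0),
        ModulationProfile("lateral_occipital_L", "high_gamma", "closure_onset", 100.0, 800.0, -15.0),
        ModulationProfile("lateral_occipital_R", "high_gamma", "closure_onset", 100.0, 800.0, -15.0),
        ModulationProfile("lateral_occipital_L", "alpha", "opening_onset", 50.0, 1000.0, -35.0),
        ModulationProfile("lateral_occipital_R", "alpha", "opening_onset", 50.0, 1000.0, -35.0),
        ModulationProfile("lateral_occipital_L", "high_gamma", "opening_onset", 50.0, 800.0, 30.0),
        ModulationProfile("lateral_occipital_R", "high_gamma", "opening_onset", 50.0, 800.0, 30.0),
    ]
    return SimConfig(n_events_per_kind=16, profiles=profiles, seed=seed)
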