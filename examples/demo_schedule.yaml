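# Flash paradigm: 60 s lights-on acclimation, then five 1 s flashes
# separated by 49 s of darkness.
paradigm: flash_series
start: 70
acclimation: 60
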