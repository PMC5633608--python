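# Carbon conversion factors (fg C per cell) per picophytoplankton group.
# "direct": compiled from unialgal cultures (min/max/average).
# "in_situ": averages back-calculated from flow-cytometric cell sizes and
# carbon:volume relationships; only averages are available, so min and max
# coincide with the average.
version: 1
direct:
  prochlorococcus: {min: 16, max: 53, average: 36}
  synechococcus: {min: 170, max: 350, average: 255}
  picoeukaryotes: {min: 800, max: 4400, average: 2590}
in_situ:
  prochlorococcus: {min: 60, max: 60, average: 60}
  synechococcus: {min: 154, max: 154, average: 154}
  picoeukaryotes: {min: 1319, max: 1319, average: 1319}
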