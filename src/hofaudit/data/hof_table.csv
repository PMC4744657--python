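structure_id,n,hof_pdb_gas,hof_pdb_aq,hof_opt_gas,hof_opt_aq
3NIR,933,-9677.2,-10043.6,-10588.31,-10838.52
3W5H,6142,-60719.18,-63125.27,-66451.1,-68066.68
3W7Y,2401,-26334.05,-27663.67,-28741.15,-29467.43
3WCQ,1715,-13737.64,-15306.84,-15253.8,-16812.44
3WDN,2818,-31166.42,-33656.06,-33933.21,-35935.5
3ZOJ,4754,-32530.8,-34379.14,-36033.83,-37029.43
4AQO,1653,-15879.93,-16890.7,-17594.74,-18379.29
4AR6,1235,-13883.15,-15511.66,-15190.45,-16644.27
4BCT,3966,-38694.79,-39895.79,-42054.08,-42859.72
4BY8,296,-1306.82,-1426.6,-1640.21,-1743.0
4EIC,1742,-15171.68,-16249.14,-16669.42,-17557.05
4FRC,4963,-41891.22,-43962.08,-46017.09,-46922.0
4FU5,5018,-40137.78,-43578.26,-44362.36,-47569.54
4G78,2802,-22818.52,-25191.37,-26087.12,-27525.25
4HGU,812,-7900.6,-8596.0,-9088.4,-9353.19
4HS1,1586,-11805.16,-13040.06,-13879.69,-14204.75
4KQP,4844,-50179.49,-52062.3,-54089.1,-55551.98
4LFS,803,-7126.4,-7851.03,-7859.9,-8328.35
4MZC,2223,-19006.0,-20433.1,-20963.86,-21833.4
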