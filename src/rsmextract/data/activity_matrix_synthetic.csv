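sample,TPC,TFC,IC50_DPPH,IC50_ABTS,IC50_tyrosinase,IC50_glucosidase,IC50_elastase
OP,24.25,23.98,87.56,172.36,59.53,221.59,372.25
HM,16.5,18.2,95.2,105.56,68.4,270.1,330.8
HE,12.1,10.9,160.3,190.4,120.6,310.2,340.9
HW,17.8,15.6,140.8,150.2,110.3,250.7,299.05
MM,13.9,12.8,150.1,180.7,115.9,298.4,352.1
ME,8.9,7.6,210.4,240.8,170.2,390.6,410.3
MW,10.2,9.1,230.9,220.3,185.7,350.9,395.4
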