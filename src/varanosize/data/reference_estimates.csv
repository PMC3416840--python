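label,group,proxy,length_mm,pcl_est_mm,ci_mm
Saniwa ensidens,all_varanus,DVL,10.9,412,17.66
V. amnhophilis,all_varanus,BCL,38.38,678.64,38.12
V. amnhophilis,indo_asian_a,BCL,38.38,712.6,83.96
V. amnhophilis,all_varanus,DVL,18,681.1,29.19
V. amnhophilis,indo_asian_a,DVL,18,664.5,36.89
V. priscus A,all_varanus,BCL,106,1874,105.3
V. priscus A,vko_vgo,BCL,106,1897,456.1
V. priscus A,komodoensis,BCL,106,1777,69.63
V. priscus B,all_varanus,DVL,53,2005,85.94
V. priscus B,vko_vgo,DVL,53,2170,211.2
V. priscus B,komodoensis,DVL,53,2116,169.6
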