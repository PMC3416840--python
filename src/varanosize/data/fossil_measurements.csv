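label,taxon,specimen_id,proxy,length_mm
Saniwa ensidens,Saniwa ensidens,,DVL,10.89
V. amnhophilis,Varanus amnhophilis,AMNH FR 30630,BCL,38.38
V. amnhophilis,Varanus amnhophilis,AMNH FR 30630,DVL,18
V. priscus A,Varanus priscus,BMNH 39965,BCL,106
V. priscus B,Varanus priscus,AMNH FR 6304,DVL,53
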