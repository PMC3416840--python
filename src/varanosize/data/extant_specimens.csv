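specimen_id,species,bcl_mm,dvl_mm,pcl_mm
AMNH R-47725,Albigularis,37,17,630
AMNH R 141072,Beccarii,18.5,8,313
AMNH R 29932,Bengalensis,25.28,14,510
AMNH R 118713,Bengalensis,30.23,17,660
AMNH R 140804,exanthematicus,28,16,470
AMNH R 77646,Flavescens,21.72,10.05,339
UF 64743,Flavescens,19,9.5,350
AMNH R 82819,Gouldii,28,14.5,650
AMNH R 74810,Griseus,20.5,9.81,423
AMNH R 142617,Indicus,12,5.5,212
AMNH R 142623,Indicus,14.58,6.93,244.44
AMNH R 37908,Komodoensis,44,19,718
AMNH R 37909,Komodoensis,87,36,1478
AMNH R 7252,Niloticus,23,9,360
AMNH R 137116,niloticus,45,25,832
AMNH R 10499,Ornatus,29.5,9,393
AMNH R 104683,Prasinus,16,8,283
AMNH R 141071,Rudicollis,13.5,6,196
AMNH R 49230,salvator?,36.5,17,660
UF 99317,Timorensis,10.5,4.5,174
UF 45363,Timorensis,10,4.5,180
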