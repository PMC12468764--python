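# Default ROI-pair predictor list: 58 connections drawn from the DIVA/GODIVA
# feedforward and feedback speech-motor control networks.
#
# NOTE: this list is a RECONSTRUCTION. The source study names the network
# family (left-lateralized DIVA/GODIVA connections plus select right-hemisphere
# connections to right vPMC and right cerebellum) and the ROI labels, but never
# enumerates the 58 pairs. This file reproduces the count, the ROI vocabulary,
# and the network logic; it is not guaranteed to match the original pair set.
#
# Labels: {L,R}_<ROI> with ROI in
#   aCb/pCb  anterior/posterior cerebellum     GP    globus pallidus
#   H        Heschl's gyrus                    MG    medial geniculate nucleus
#   pAC      posterior auditory cortex         pIFS  posterior inferior frontal sulcus
#   preSMA   presupplementary motor area       pSTG  posterior superior temporal gyrus
#   PT       planum temporale                  SMA   supplementary motor area
#   VA/VL    ventral anterior/lateral thalamus vMC   ventral motor cortex
#   vPMC     ventral premotor cortex           VPM   ventral posterior medial thalamus
#   vSC      ventral somatosensory cortex
#
# GODIVA planning loop (left)
- [L_pIFS, L_preSMA]
- [L_pIFS, L_vPMC]
- [L_preSMA, L_SMA]
- [L_pIFS, L_GP]
- [L_preSMA, L_GP]
- [L_GP, L_VA]
- [L_VA, L_pIFS]
- [L_VA, L_preSMA]
- [L_VA, L_vPMC]
# DIVA feedforward motor loop (left)
- [L_vPMC, L_vMC]
- [L_SMA, L_vMC]
- [L_preSMA, L_vMC]
- [L_vPMC, L_aCb]
- [L_aCb, L_VL]
- [L_VL, L_vMC]
- [L_SMA, L_VL]
- [L_vPMC, L_VL]
- [L_vMC, L_aCb]
- [L_vMC, L_GP]
- [L_vPMC, L_GP]
- [L_vPMC, L_pCb]
- [L_pCb, L_VL]
- [L_pCb, L_pIFS]
# auditory feedback pathway (left)
- [L_MG, L_H]
- [L_MG, L_pAC]
- [L_H, L_pAC]
- [L_H, L_pSTG]
- [L_H, L_PT]
- [L_pAC, L_pSTG]
- [L_pSTG, L_PT]
- [L_vMC, L_pAC]
- [L_vMC, L_pSTG]
- [L_vMC, L_PT]
- [L_pAC, L_vPMC]
- [L_pSTG, L_vPMC]
- [L_PT, L_vPMC]
- [L_pSTG, L_pIFS]
# somatosensory feedback pathway (left)
- [L_VPM, L_vSC]
- [L_vSC, L_vMC]
- [L_vSC, L_vPMC]
- [L_vSC, L_pSTG]
# feedback control map in right vPMC
- [L_vMC, R_vPMC]
- [L_vPMC, R_vPMC]
- [L_pAC, R_vPMC]
- [L_pSTG, R_vPMC]
- [L_PT, R_vPMC]
- [L_H, R_vPMC]
- [L_vSC, R_vPMC]
- [L_pIFS, R_vPMC]
- [L_preSMA, R_vPMC]
- [L_SMA, R_vPMC]
# right cerebellar connections
- [R_aCb, L_VL]
- [R_aCb, L_vMC]
- [R_aCb, L_vPMC]
- [R_aCb, L_SMA]
- [R_aCb, R_vPMC]
- [R_pCb, L_pIFS]
- [R_pCb, L_preSMA]
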